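"""Readers and writers for every external format the pipeline touches.

All coordinates are normalized exactly once, here: GTF/GFF3 and the domain
TSV are 1-based inclusive on disk and 0-based half-open in memory.  Events
TSVs are written (and read back) in the internal convention, documented in
their header comment.
"""

from __future__ import annotations

import logging
import textwrap
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
import pyfaidx
from gffutils.feature import feature_from_line

from .models import (
    AltExonEvent,
    DomainHit,
    EVENT_CLASSES,
    GeneAnnotationSet,
    GenomeInterval,
    PathwayCollection,
    TranscriptModel,
    normalize_symbol,
)

log = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "probeset_id",
    "gene_symbol",
    "chrom",
    "start",
    "end",
    "strand",
    "event_class",
    "host_transcript_id",
    "SI",
    "FC",
]

DOMAIN_COLUMNS = [
    "protein_key",
    "accession",
    "name",
    "description",
    "res_start",
    "res_end",
]


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# genome FASTA
# ---------------------------------------------------------------------------


def read_genome(path) -> pyfaidx.Fasta:
    """Open a genome FASTA with an on-disk index (created if missing)."""
    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def fetch(genome: pyfaidx.Fasta, interval: GenomeInterval) -> str:
    """Plus-strand sequence of ``interval`` (orientation handled by callers)."""
    return str(genome[interval.chrom][interval.start : interval.end])


def write_fasta(path, records: Dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for line in textwrap.wrap(seq, width):
                fh.write(line + "\n")


# ---------------------------------------------------------------------------
# transcript models (GTF / GFF3)
# ---------------------------------------------------------------------------


def _attr(feature, *names: str) -> Optional[str]:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def read_transcripts(path) -> List[TranscriptModel]:
    """Parse exon/CDS features of a GTF or GFF3 file into transcript models.

    File coordinates (1-based inclusive) are converted to 0-based half-open.
    Transcripts without CDS are retained and flagged non-coding via an empty
    ``cds`` list.
    """
    exons: Dict[str, List[GenomeInterval]] = {}
    cds: Dict[str, List[GenomeInterval]] = {}
    meta: Dict[str, Tuple[str, str, str, str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(
                    f"{path}: malformed line {lineno}: expected 9 tab-separated "
                    "fields"
                )
            try:
                feature = feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise FormatError(f"{path}: malformed line {lineno}: {exc}") from exc
            if feature.featuretype not in ("exon", "CDS"):
                continue
            tid = _attr(feature, "transcript_id", "Parent")
            if tid is None:
                raise FormatError(
                    f"{path}: line {lineno}: {feature.featuretype} feature "
                    "lacks transcript_id/Parent"
                )
            gid = _attr(feature, "gene_id", "geneID", "gene") or tid
            sym = _attr(feature, "gene_name", "gene_symbol", "Name") or gid
            if feature.strand not in ("+", "-"):
                raise FormatError(f"{path}: line {lineno}: missing strand")
            interval = GenomeInterval(
                feature.seqid, feature.start - 1, feature.end, feature.strand
            )
            meta.setdefault(tid, (gid, sym, feature.seqid, feature.strand))
            bucket = exons if feature.featuretype == "exon" else cds
            bucket.setdefault(tid, []).append(interval)

    transcripts = []
    for tid, (gid, sym, chrom, strand) in meta.items():
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            gene_symbol=sym,
            chrom=chrom,
            strand=strand,
            exons=sorted(exons.get(tid, []), key=lambda x: x.start),
            cds=sorted(cds.get(tid, []), key=lambda x: x.start),
        )
        try:
            model.validate()
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        transcripts.append(model)
    return transcripts


def write_gtf(path, transcripts: Sequence[TranscriptModel]) -> None:
    """Write transcripts as GTF (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_name "{t.gene_symbol}";'
            )
            for ftype, part in (("exon", t.exons), ("CDS", t.cds)):
                for g in part:
                    fh.write(
                        "\t".join(
                            [
                                t.chrom,
                                "spliceimpact",
                                ftype,
                                str(g.start + 1),
                                str(g.end),
                                ".",
                                t.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# DAS event table
# ---------------------------------------------------------------------------


def read_events(path) -> List[AltExonEvent]:
    """Read the DAS event TSV (header required, internal 0-based coordinates)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    events = []
    for idx, row in df.iterrows():
        if row["event_class"] not in EVENT_CLASSES:
            raise FormatError(
                f"{path}: row {idx + 2}: unknown event_class "
                f"{row['event_class']!r}; allowed: {', '.join(EVENT_CLASSES)}"
            )
        try:
            si = float(row["SI"])
            fc = float(row["FC"])
        except ValueError as exc:
            raise FormatError(f"{path}: row {idx + 2}: non-numeric SI/FC") from exc
        host = row["host_transcript_id"]
        events.append(
            AltExonEvent(
                probeset_id=row["probeset_id"],
                gene_symbol=row["gene_symbol"],
                region=GenomeInterval(
                    row["chrom"], int(row["start"]), int(row["end"]), row["strand"]
                ),
                event_class=row["event_class"],
                host_transcript_id="" if pd.isna(host) else host,
                SI=si,
                FC=fc,
            )
        )
    return events


def write_events(path, events: Sequence[AltExonEvent]) -> None:
    rows = [
        {
            "probeset_id": e.probeset_id,
            "gene_symbol": e.gene_symbol,
            "chrom": e.region.chrom,
            "start": e.region.start,
            "end": e.region.end,
            "strand": e.region.strand,
            "event_class": e.event_class,
            "host_transcript_id": e.host_transcript_id,
            "SI": f"{e.SI:.4f}",
            "FC": f"{e.FC:.4f}",
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# domain hits
# ---------------------------------------------------------------------------


def read_domains(path) -> List[DomainHit]:
    """Read domain hits; file residues are 1-based inclusive, internal 0-based."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    hits = []
    for idx, row in df.iterrows():
        start1 = int(row["res_start"])
        end1 = int(row["res_end"])
        if not (1 <= start1 <= end1):
            raise FormatError(
                f"{path}: row {idx + 2}: invalid residue range {start1}..{end1}"
            )
        hits.append(
            DomainHit(
                protein_key=row["protein_key"],
                accession=row["accession"],
                name=row["name"],
                description=row["description"],
                res_start=start1 - 1,
                res_end=end1,
            )
        )
    return hits


def write_domains(path, hits: Sequence[DomainHit]) -> None:
    rows = [
        {
            "protein_key": h.protein_key,
            "accession": h.accession,
            "name": h.name,
            "description": h.description,
            "res_start": h.res_start + 1,
            "res_end": h.res_end,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=DOMAIN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO annotations (2-column TSV or GAF 2.x)
# ---------------------------------------------------------------------------


def read_go(path) -> GeneAnnotationSet:
    """Read gene -> GO annotations.

    Two dialects are accepted:

    * 2-column TSV ``gene<TAB>term name`` (primary; carries the term names the
      token-overlap filter works on);
    * GAF 2.x, in which case column 5 (a GO identifier) is stored as the term
      string, because GAF does not carry term names.
    """
    ann = GeneAnnotationSet()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF 2.x record
                gene, term = fields[2], fields[4]
                go_id = fields[4]
            elif len(fields) >= 2:
                gene, term = fields[0], fields[1]
                go_id = fields[2] if len(fields) > 2 else None
            else:
                raise FormatError(f"{path}: line {lineno}: expected >=2 columns")
            if not gene.strip() or not term.strip():
                raise FormatError(f"{path}: line {lineno}: empty gene or term")
            key = normalize_symbol(gene)
            ann.terms.setdefault(key, set()).add(term.strip())
            if go_id:
                ann.identifiers.setdefault(key, set()).add(go_id.strip())
    return ann


def write_go(path, ann: GeneAnnotationSet) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann.terms):
            for term in sorted(ann.terms[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# pathway gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path) -> PathwayCollection:
    coll = PathwayCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT needs id, description, >=1 gene"
                )
            pid, name = fields[0], fields[1]
            genes = {normalize_symbol(g) for g in fields[2:] if g.strip()}
            if not genes:
                raise FormatError(f"{path}: line {lineno}: empty gene set {pid!r}")
            if pid in coll.pathways:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
            coll.pathways[pid] = (name, genes)
    return coll


def write_gmt(path, coll: PathwayCollection) -> None:
    with open(path, "w") as fh:
        for pid, (name, genes) in coll.pathways.items():
            fh.write("\t".join([pid, name] + sorted(genes)) + "\n")
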