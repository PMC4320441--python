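"""Core domain types shared by every stage of the pipeline.

Coordinate conventions
----------------------
* Genomic coordinates: 0-based half-open, strand one of ``+``/``-``.
* Residue coordinates: 0-based half-open on the *inclusion* (reference)
  protein.
* File formats keep their native conventions (GTF/GFF3 and the domain TSV are
  1-based inclusive); conversion happens exactly once, in :mod:`.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

from . import intervals as iv

EVENT_CLASSES = (
    "skipped_exon",
    "alt_5ss",
    "alt_3ss",
    "intron_retention",
    "alt_promoter",
    "alt_polyA",
    "complex",
)

REGION_CLASSES = ("coding", "utr_only", "mixed", "not_determined")
DOMAIN_STATUS_VALUES = ("intact", "internally_altered", "truncated", "lost")
AFFECTED_REGIONS = ("domain", "n_term", "c_term", "linker", "none")
CODING_STATUSES = ("coding", "non_coding", "premature_stop_flagged")


def normalize_symbol(symbol: str) -> str:
    """Case-insensitive gene-symbol key (mouse Egfr and human EGFR unify)."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GenomeInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """Ordered exon/CDS structure of one transcript.

    ``exons`` and ``cds`` are sorted by genomic start and pairwise
    non-overlapping; every CDS interval lies inside the exon union.  CDS
    intervals include the stop codon when one is annotated.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    exons: List[GenomeInterval] = field(default_factory=list)
    cds: List[GenomeInterval] = field(default_factory=list)

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        for part in (self.exons, self.cds):
            for a in part:
                if a.chrom != self.chrom or a.strand != self.strand:
                    raise ValueError(
                        f"{self.transcript_id}: interval on wrong chrom/strand"
                    )
        spans = [e.span for e in self.exons]
        if spans != sorted(spans):
            raise ValueError(f"{self.transcript_id}: exons not sorted")
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        for c in self.cds:
            if not iv.covers(spans, c.span):
                raise ValueError(
                    f"{self.transcript_id}: CDS {c.start}-{c.end} outside exons"
                )

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def exon_spans(self) -> List[Tuple[int, int]]:
        return [e.span for e in self.exons]

    @property
    def cds_spans(self) -> List[Tuple[int, int]]:
        return [c.span for c in self.cds]

    def cds_length(self) -> int:
        return iv.total_length(self.cds_spans)


@dataclass
class AltExonEvent:
    """One differentially alternatively spliced exon/region.

    SI (splicing index) and FC (fold change) come from the upstream
    differential-exon study and are carried as metadata only.
    """

    probeset_id: str
    gene_symbol: str
    region: GenomeInterval
    event_class: str
    host_transcript_id: str = ""
    SI: float = 0.0
    FC: float = 0.0

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(
                f"unknown event_class {self.event_class!r}; "
                f"allowed: {', '.join(EVENT_CLASSES)}"
            )


@dataclass
class TranscriptPair:
    """Inclusion (region present) and exclusion (region absent) isoforms."""

    event: AltExonEvent
    inclusion: TranscriptModel
    exclusion: TranscriptModel


@dataclass(frozen=True)
class DomainHit:
    """A conserved-domain interval on the inclusion protein, with free text."""

    protein_key: str
    accession: str
    name: str
    description: str
    res_start: int
    res_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.res_start < self.res_end):
            raise ValueError(
                f"{self.accession}: invalid residue interval "
                f"[{self.res_start}, {self.res_end})"
            )


@dataclass
class ProteinRecord:
    """Translation product of one transcript (no stop symbol)."""

    sequence: str
    coding_status: str
    cds_used: List[GenomeInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ResidueDiff:
    """Block-level difference between inclusion and exclusion proteins.

    The altered block is everything between the longest common prefix and the
    longest common suffix of the two sequences (suffix capped so that
    prefix + suffix never exceeds the shorter length).
    """

    prefix_len: int
    suffix_len: int
    len_incl: int
    len_excl: int

    @property
    def altered_incl(self) -> int:
        return self.len_incl - self.prefix_len - self.suffix_len

    @property
    def altered_excl(self) -> int:
        return self.len_excl - self.prefix_len - self.suffix_len

    @property
    def n_altered(self) -> int:
        return max(self.altered_incl, self.altered_excl)

    @property
    def frac_altered(self) -> float:
        denom = max(self.len_incl, self.len_excl)
        return self.n_altered / denom if denom else 0.0

    @property
    def protein_changed(self) -> bool:
        return self.n_altered > 0


@dataclass(frozen=True)
class DomainStatus:
    domain: DomainHit
    status: str

    def __post_init__(self) -> None:
        if self.status not in DOMAIN_STATUS_VALUES:
            raise ValueError(f"unknown domain status {self.status!r}")


@dataclass
class ImpactRecord:
    """Per-event classification; the row type of the central impact table."""

    event: AltExonEvent
    region_class: str = "not_determined"
    protein_changed: bool = False
    domain_changed: bool = False
    affected_region: str = "none"
    domain_statuses: List[DomainStatus] = field(default_factory=list)
    overlap_tokens: Set[str] = field(default_factory=set)
    passes_overlap_filter: bool = False
    diff: Optional[ResidueDiff] = None
    coding_status_incl: str = "non_coding"
    coding_status_excl: str = "non_coding"


@dataclass
class GeneAnnotationSet:
    """gene symbol (normalized) -> set of GO term names (free text)."""

    terms: Dict[str, Set[str]] = field(default_factory=dict)
    identifiers: Dict[str, Set[str]] = field(default_factory=dict)

    def genes(self) -> Set[str]:
        return set(self.terms)

    def terms_for(self, symbol: str) -> Set[str]:
        return self.terms.get(normalize_symbol(symbol), set())


@dataclass
class PathwayCollection:
    """pathway id -> (display name, set of normalized gene symbols)."""

    pathways: Dict[str, Tuple[str, Set[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def items(self):
        return self.pathways.items()


@dataclass
class EnrichmentResult:
    pathway_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    significant: bool
    members: List[str] = field(default_factory=list)


@dataclass
class FunnelReport:
    """Stage-by-stage counts of the annotation funnel."""

    n_events: int = 0
    n_failed: int = 0
    n_protein_changed: int = 0
    n_domain_changed: int = 0
    n_overlap_probesets: int = 0
    n_overlap_genes: int = 0
    region_class_breakdown: Dict[str, int] = field(default_factory=dict)
    top_pathway: Optional[EnrichmentResult] = None
    failure_reasons: Dict[str, int] = field(default_factory=dict)
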