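"""Deterministic synthetic fixture generator with machine-readable truth.

The generator builds complete toy datasets — genome FASTA, transcript GTF,
DAS event table, domain hits, GO annotations and pathway GMT — in which every
event's expected labels are known at generation time.  Design rules that make
the truth analytic:

* All non-planted sequence is drawn from the ``{C, G, T}`` alphabet, so start
  (ATG) and stop codons occur only where planted.
* Planted deletions/insertions are multiples of 3 nt: fixtures contain no
  frameshifts (frameshift handling is exercised by hand-built unit fixtures).
* Genes are built in mRNA space first; proteins and truth labels are computed
  there with the generator's own per-residue logic, independent of the
  pipeline's genomic-coordinate path, then the gene is laid onto a contig
  (reverse-complemented for minus-strand genes, which alternate with plus).

Defaults emulate the proportions a differential-splicing screen of this kind
reports: roughly half of protein-changing events touching an annotated
domain, roughly 40% of changed-domain genes sharing a token between domain
description and GO term, and ~10% of exon-skipping placements in the 3' UTR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io as sio
from .models import (
    AltExonEvent,
    DomainHit,
    GeneAnnotationSet,
    GenomeInterval,
    PathwayCollection,
    TranscriptModel,
    normalize_symbol,
)

DEFAULT_EVENT_MIX: Dict[str, float] = {
    "skipped_exon": 0.30,
    "alt_5ss": 0.08,
    "alt_3ss": 0.08,
    "intron_retention": 0.12,
    "alt_promoter": 0.14,
    "alt_polyA": 0.18,
    "complex": 0.10,
}

#: fraction of skipped-exon placements that land in the 3' UTR
UTR_PLACEMENT_FRAC = 0.10

_SAFE = np.array(list("CGT"))
_STOPS = ("TAA", "TAG", "TGA")

_DOMAIN_ADJ = ("serine", "zinc", "atp", "calcium", "rho", "tyrosine")
_DOMAIN_NOUN = (
    "kinase",
    "helicase",
    "phosphatase",
    "transporter",
    "protease",
    "synthase",
)
# GO vocabulary token-disjoint from the domain vocabulary above
_GO_VOCAB = (
    "membrane organization",
    "vesicle trafficking",
    "chromatin remodeling",
    "lipid storage",
    "axon guidance",
    "cilium assembly",
    "rna localization",
    "cell adhesion",
)


class FixtureError(ValueError):
    """Raised for infeasible fixture specifications."""


@dataclass
class FixtureSpec:
    """Conditions the generated dataset emulates."""

    n_genes: int = 236
    exons_per_gene: Tuple[int, int] = (3, 10)
    event_class_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_MIX)
    )
    frac_domain_affecting: float = 0.53
    frac_overlap_pass: float = 0.38
    planted_pathway_size: int = 15
    planted_pathway_hits: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise FixtureError("n_genes must be positive")
        lo, hi = self.exons_per_gene
        if not (2 <= lo <= hi):
            raise FixtureError("exons_per_gene must satisfy 2 <= lo <= hi")
        for name, p in list(self.event_class_mix.items()) + [
            ("frac_domain_affecting", self.frac_domain_affecting),
            ("frac_overlap_pass", self.frac_overlap_pass),
        ]:
            if not (0.0 <= p <= 1.0):
                raise FixtureError(f"probability {name}={p} outside [0, 1]")
        if abs(sum(self.event_class_mix.values()) - 1.0) > 1e-9:
            raise FixtureError("event_class_mix must sum to 1")
        if self.planted_pathway_hits > self.planted_pathway_size:
            raise FixtureError("planted_pathway_hits exceeds planted_pathway_size")


@dataclass
class FixturePaths:
    genome: Path
    gtf: Path
    events: Path
    domains: Path
    go: Path
    gmt: Path
    truth: Path
    summary: Path


# ---------------------------------------------------------------------------
# sequence helpers (generator-local, mRNA space)
# ---------------------------------------------------------------------------


def _safe(rng: np.random.Generator, n: int) -> str:
    """Random sequence over {C,G,T}: no ATG, no stop codon can occur."""
    return "".join(rng.choice(_SAFE, size=n))


def _translate(mrna: str, start: int) -> str:
    """Translate from ``start`` to the first in-frame stop (or mRNA end)."""
    usable = start + (len(mrna) - start) // 3 * 3
    aa = str(Seq(mrna[start:usable]).translate())
    cut = aa.find("*")
    return aa if cut < 0 else aa[:cut]


def _prefix_suffix(a: str, b: str) -> Tuple[int, int]:
    p = 0
    while p < min(len(a), len(b)) and a[p] == b[p]:
        p += 1
    cap = min(len(a), len(b)) - p
    s = 0
    while s < cap and a[len(a) - 1 - s] == b[len(b) - 1 - s]:
        s += 1
    return p, s


def _domain_status_sets(
    dom: Tuple[int, int], absent: Set[int], prefix: int, suffix: int
) -> str:
    """Per-residue (set based) status call used for truth labels."""
    ds, de = dom
    dres = set(range(ds, de))
    hit = dres & absent
    if not hit:
        return "intact"
    if hit == dres:
        return "lost"
    if suffix == 0 and ds < prefix < de:
        return "truncated"
    return "internally_altered"


def _affected_region(
    domains: Sequence[Tuple[int, int]],
    statuses: Sequence[str],
    prefix: int,
    suffix: int,
    len_incl: int,
    protein_changed: bool,
) -> str:
    if not protein_changed:
        return "none"
    if any(s != "intact" for s in statuses):
        return "domain"
    bs, be = prefix, len_incl - suffix
    lo, hi = (bs, bs + 1) if bs == be else (bs, be)
    if domains:
        first = min(d[0] for d in domains)
        last = max(d[1] for d in domains)
        if hi <= first:
            return "n_term"
        if lo >= last:
            return "c_term"
        return "linker"
    if lo == 0:
        return "n_term"
    if hi >= len_incl:
        return "c_term"
    return "linker"


def _allocate_classes(mix: Dict[str, float], n: int, rng) -> List[str]:
    """Deterministic largest-remainder allocation; each class gets >= 1."""
    classes = [c for c, p in mix.items() if p > 0]
    if n < len(classes):
        counts = {c: 0 for c in classes}
        for i, c in enumerate(classes[:n]):
            counts[c] = 1
    else:
        raw = {c: mix[c] * n for c in classes}
        counts = {c: max(1, int(raw[c])) for c in classes}
        rem = n - sum(counts.values())
        order = sorted(classes, key=lambda c: raw[c] - int(raw[c]), reverse=True)
        i = 0
        while rem > 0:
            counts[order[i % len(order)]] += 1
            i += 1
            rem -= 1
        while rem < 0:
            cand = max(counts, key=lambda c: counts[c])
            counts[cand] -= 1
            rem += 1
    out: List[str] = []
    for c in classes:
        out.extend([c] * counts[c])
    out = out[:n]
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# per-gene construction
# ---------------------------------------------------------------------------


@dataclass
class _Gene:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    contig: str
    transcripts: List[TranscriptModel]
    event: AltExonEvent
    incl_protein: str
    excl_protein: str
    region_class: str
    domains: List[DomainHit]
    statuses: List[str]
    protein_changed: bool
    domain_changed: bool
    affected_region: str
    passes_overlap: bool
    go_terms: List[str]


def _build_gene(idx: int, cls: str, spec: FixtureSpec, rng) -> _Gene:
    gene_id = f"G{idx:05d}"
    symbol = f"GENE{idx:05d}"
    tx_id = f"T{idx:05d}.1"
    chrom = f"chr{idx:05d}"
    strand = "+" if idx % 2 == 0 else "-"

    ncod = int(rng.integers(60, 151))
    u5 = int(rng.integers(9, 31))
    utr_case = cls == "skipped_exon" and rng.random() < UTR_PLACEMENT_FRAC
    u3 = int(rng.integers(30, 46)) if utr_case else int(rng.integers(18, 41))
    codons = [_safe(rng, 3) for _ in range(ncod)]

    cds_start = u5
    cds_end = u5 + 3 * (ncod + 2)  # includes the stop codon

    def codon_pos(c: int) -> int:
        return u5 + 3 * c

    cuts: Set[int] = set()
    avoid: List[Tuple[int, int]] = []  # zones where extra cuts are forbidden
    region_mrna: Optional[Tuple[int, int]] = None
    intron_at: Optional[Tuple[int, int]] = None  # (junction offset, length)
    planted_atg_codon: Optional[int] = None
    region_class = "coding"

    if cls in ("skipped_exon", "complex") and not utr_case:
        k = int(rng.integers(4, 13))
        d = int(rng.integers(0, 3))
        a = int(rng.integers(8, ncod - k - 8))
        r0 = codon_pos(a) + d
        region_mrna = (r0, r0 + 3 * k)
        cuts |= set(region_mrna)
        avoid.append((r0 - 6, r0 + 3 * k + 6))
    elif utr_case:
        r0 = cds_end + int(rng.integers(3, 8))
        rl = int(rng.integers(8, 16))
        region_mrna = (r0, r0 + rl)
        cuts |= set(region_mrna)
        avoid.append((r0 - 6, r0 + rl + 6))
        region_class = "utr_only"
    elif cls == "alt_5ss":
        k = int(rng.integers(2, 7))
        a = int(rng.integers(k + 6, ncod - 8))
        q = codon_pos(a) + int(rng.integers(0, 3))
        region_mrna = (q - 3 * k, q)
        cuts.add(q)
        avoid.append((q - 3 * k - 6, q + 6))
    elif cls == "alt_3ss":
        k = int(rng.integers(2, 7))
        a = int(rng.integers(8, ncod - k - 8))
        q = codon_pos(a) + int(rng.integers(0, 3))
        region_mrna = (q, q + 3 * k)
        cuts.add(q)
        avoid.append((q - 6, q + 3 * k + 6))
    elif cls == "intron_retention":
        k = int(rng.integers(3, 11))
        a = int(rng.integers(8, ncod - 8))
        q = codon_pos(a) + int(rng.integers(0, 3))
        cuts.add(q)
        intron_at = (q, 3 * k)
        avoid.append((q - 6, q + 6))
    elif cls == "alt_promoter":
        c = int(rng.integers(3, 9))
        e1 = codon_pos(c)
        j = int(rng.integers(c + 3, ncod - 30))
        codons[j - 1] = "ATG"  # codon index j (codon 0 is the start ATG)
        planted_atg_codon = j
        region_mrna = (0, e1)
        cuts.add(e1)
        avoid.append((0, e1 + 6))
        region_class = "mixed"
    elif cls == "alt_polyA":
        m = int(rng.integers(10, ncod - 4))
        p0 = codon_pos(m)
        p1 = cds_end + 6
        region_mrna = (p0, p1)
        cuts |= {p0, p1}
        avoid.append((p0 - 6, p1 + 6))
        region_class = "mixed"
    else:  # pragma: no cover
        raise FixtureError(f"unhandled class {cls}")

    mrna = _safe(rng, u5) + "ATG" + "".join(codons) + "TAA" + _safe(rng, u3)
    mlen = len(mrna)

    # exon segmentation: mandatory cuts plus random extras up to the target
    lo, hi = spec.exons_per_gene
    target_exons = int(rng.integers(lo, hi + 1))
    target_exons = max(target_exons, len(cuts) + 1)
    tries = 0
    while len(cuts) + 1 < target_exons and tries < 200:
        tries += 1
        pos = int(rng.integers(6, mlen - 6))
        if any(zs <= pos < ze for zs, ze in avoid):
            continue
        if any(abs(pos - c) < 6 for c in cuts):
            continue
        cuts.add(pos)
    boundaries = [0] + sorted(cuts) + [mlen]
    exon_mrna = list(zip(boundaries[:-1], boundaries[1:]))

    # inclusion / exclusion mRNAs and proteins (generator-local semantics)
    incl_mrna = mrna
    if intron_at is not None:
        q, ilen = intron_at
        retained = _safe(rng, ilen)
        incl_mrna = mrna[:q] + retained + mrna[q:]
    incl_protein = _translate(incl_mrna, cds_start)

    if intron_at is not None:
        excl_protein = _translate(mrna, cds_start)
    elif cls == "alt_promoter":
        assert region_mrna is not None
        tail = mrna[region_mrna[1] :]
        i = tail.find("ATG")
        excl_protein = _translate(tail, i) if i >= 0 else ""
    elif cls == "alt_polyA":
        assert region_mrna is not None
        excl_protein = _translate(mrna[: region_mrna[0]], cds_start)
    else:
        assert region_mrna is not None
        r0, r1 = region_mrna
        excl_protein = _translate(mrna[:r0] + mrna[r1:], cds_start)

    prefix, suffix = _prefix_suffix(incl_protein, excl_protein)
    L = len(incl_protein)
    n_altered = max(L, len(excl_protein)) - prefix - suffix
    protein_changed = n_altered > 0
    absent = set(range(prefix, L - suffix))

    # domain placement on the inclusion protein
    affecting = protein_changed and rng.random() < spec.frac_domain_affecting
    dom_spans: List[Tuple[int, int]] = []
    dom_meta: List[Tuple[str, str]] = []  # (adj, noun)
    n_dom = int(rng.integers(1, 4))
    bs, be = prefix, L - suffix
    if affecting:
        ds = max(0, bs - int(rng.integers(0, 4)))
        de = min(L, bs + int(rng.integers(2, 9)))
        if de <= ds:
            ds = max(0, de - 3)
        dom_spans.append((ds, de))
    zones = [(0, bs), (be, L)] if protein_changed else [(0, L)]
    while len(dom_spans) < n_dom:
        open_zones = [(zs, ze) for zs, ze in zones if ze - zs >= 8]
        if not open_zones:
            break
        zs, ze = open_zones[int(rng.integers(0, len(open_zones)))]
        length = int(rng.integers(5, 15))
        length = min(length, ze - zs - 1)
        ds = zs + int(rng.integers(0, ze - zs - length))
        dom_spans.append((ds, ds + length))
    for _ in dom_spans:
        dom_meta.append(
            (
                _DOMAIN_ADJ[int(rng.integers(0, len(_DOMAIN_ADJ)))],
                _DOMAIN_NOUN[int(rng.integers(0, len(_DOMAIN_NOUN)))],
            )
        )

    statuses = [
        _domain_status_sets(d, absent, prefix, suffix) for d in dom_spans
    ]
    domain_changed = any(s != "intact" for s in statuses)
    affected = _affected_region(
        dom_spans, statuses, prefix, suffix, L, protein_changed
    )

    # GO terms and the overlap-filter truth
    base_terms = list(
        rng.choice(np.array(_GO_VOCAB), size=int(rng.integers(2, 4)), replace=False)
    )
    passes = False
    if domain_changed:
        if rng.random() < spec.frac_overlap_pass:
            changed_idx = next(
                i for i, s in enumerate(statuses) if s != "intact"
            )
            base_terms.append(f"{dom_meta[changed_idx][1]} activity")
            passes = True

    domains = [
        DomainHit(
            protein_key=symbol,
            accession=f"SD{idx:05d}{chr(65 + di)}",
            name=f"{adj.capitalize()}_{noun}",
            description=f"{adj} {noun} domain",
            res_start=ds,
            res_end=de,
        )
        for di, ((ds, de), (adj, noun)) in enumerate(zip(dom_spans, dom_meta))
    ]

    # --- genomic layout (plus orientation first) ---
    left_pad = _safe(rng, int(rng.integers(10, 21)))
    right_pad = _safe(rng, int(rng.integers(10, 21)))
    pieces = [left_pad]
    pos = len(left_pad)
    exon_genomic: List[Tuple[int, int]] = []
    intron_region_plus: Optional[Tuple[int, int]] = None
    for ei, (es, ee) in enumerate(exon_mrna):
        pieces.append(mrna[es:ee])
        exon_genomic.append((pos, pos + (ee - es)))
        pos += ee - es
        if ei < len(exon_mrna) - 1:
            junction = exon_mrna[ei][1]
            if intron_at is not None and junction == intron_at[0]:
                iseq = retained
                intron_region_plus = (pos, pos + len(iseq))
            else:
                iseq = _safe(rng, int(rng.integers(35, 76)))
            pieces.append(iseq)
            pos += len(iseq)
    pieces.append(right_pad)
    contig_plus = "".join(pieces)
    clen = len(contig_plus)

    def mrna_to_plus(interval: Tuple[int, int]) -> List[Tuple[int, int]]:
        out = []
        for (es, ee), (gs, ge) in zip(exon_mrna, exon_genomic):
            s = max(interval[0], es)
            e = min(interval[1], ee)
            if s < e:
                out.append((gs + (s - es), gs + (e - es)))
        return out

    cds_plus = mrna_to_plus((cds_start, cds_end))
    if region_mrna is not None:
        region_plus_parts = mrna_to_plus(region_mrna)
        region_plus = (region_plus_parts[0][0], region_plus_parts[-1][1])
    else:
        assert intron_region_plus is not None
        region_plus = intron_region_plus

    if strand == "+":
        contig = contig_plus
        flip = lambda t: t
    else:
        contig = str(Seq(contig_plus).reverse_complement())
        flip = lambda t: (clen - t[1], clen - t[0])

    mk = lambda spans: [
        GenomeInterval(chrom, s, e, strand) for s, e in sorted(flip(t) for t in spans)
    ]
    base_tx = TranscriptModel(
        transcript_id=tx_id,
        gene_id=gene_id,
        gene_symbol=symbol,
        chrom=chrom,
        strand=strand,
        exons=mk(exon_genomic),
        cds=mk(cds_plus),
    )
    base_tx.validate()
    transcripts = [base_tx]

    host_field = tx_id
    if cls == "complex":
        # second annotated transcript = base minus the region exon
        alt_id = f"T{idx:05d}.2"
        assert region_mrna is not None
        ex2 = [t for t in exon_genomic if mrna_to_plus(region_mrna)[0] != t]
        region_p = mrna_to_plus(region_mrna)[0]
        cds2 = [
            t
            for t in cds_plus
            if not (t[0] < region_p[1] and region_p[0] < t[1])
        ]
        alt_tx = TranscriptModel(
            transcript_id=alt_id,
            gene_id=gene_id,
            gene_symbol=symbol,
            chrom=chrom,
            strand=strand,
            exons=mk(ex2),
            cds=mk(cds2),
        )
        alt_tx.validate()
        transcripts.append(alt_tx)
        host_field = f"{tx_id}|{alt_id}"

    rs, re_ = flip(region_plus)
    event = AltExonEvent(
        probeset_id=f"PSR{idx:05d}",
        gene_symbol=symbol,
        region=GenomeInterval(chrom, rs, re_, strand),
        event_class=cls,
        host_transcript_id=host_field,
        SI=round(float(rng.normal(0.0, 1.2)), 4),
        FC=round(float(2.0 ** rng.normal(0.0, 1.0)), 4),
    )

    return _Gene(
        gene_id=gene_id,
        symbol=symbol,
        chrom=chrom,
        strand=strand,
        contig=contig,
        transcripts=transcripts,
        event=event,
        incl_protein=incl_protein,
        excl_protein=excl_protein,
        region_class=region_class,
        domains=domains,
        statuses=statuses,
        protein_changed=protein_changed,
        domain_changed=domain_changed,
        affected_region=affected,
        passes_overlap=passes,
        go_terms=base_terms,
    )


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------


def generate(spec: FixtureSpec, out_dir) -> FixturePaths:
    """Write a complete fixture set plus truth tables into ``out_dir``."""
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    classes = _allocate_classes(spec.event_class_mix, spec.n_genes, rng)
    genes = [_build_gene(i, cls, spec, rng) for i, cls in enumerate(classes)]

    # pathway collection with one planted over-represented pathway
    passing = sorted(g.symbol for g in genes if g.passes_overlap)
    all_symbols = sorted(g.symbol for g in genes)
    if spec.planted_pathway_hits > len(passing):
        raise FixtureError(
            f"planted_pathway_hits={spec.planted_pathway_hits} exceeds the "
            f"{len(passing)} genes passing the overlap filter"
        )
    hits = sorted(
        rng.choice(np.array(passing), size=spec.planted_pathway_hits, replace=False)
    )
    non_hits = [s for s in all_symbols if s not in set(hits)]
    fill = sorted(
        rng.choice(
            np.array(non_hits),
            size=spec.planted_pathway_size - spec.planted_pathway_hits,
            replace=False,
        )
    )
    coll = PathwayCollection()
    coll.pathways["PW_PLANTED"] = (
        "planted signaling pathway",
        {normalize_symbol(s) for s in list(hits) + fill},
    )
    n_decoys = 10
    for di in range(n_decoys):
        members = rng.choice(
            np.array(all_symbols),
            size=min(spec.planted_pathway_size, len(all_symbols)),
            replace=False,
        )
        coll.pathways[f"PW_DECOY{di:02d}"] = (
            f"decoy pathway {di:02d}",
            {normalize_symbol(s) for s in members},
        )

    ann = GeneAnnotationSet()
    for g in genes:
        ann.terms[normalize_symbol(g.symbol)] = set(g.go_terms)

    paths = FixturePaths(
        genome=out / "genome.fa",
        gtf=out / "annotation.gtf",
        events=out / "events.tsv",
        domains=out / "domains.tsv",
        go=out / "go.tsv",
        gmt=out / "pathways.gmt",
        truth=out / "truth_events.tsv",
        summary=out / "truth_summary.json",
    )
    sio.write_fasta(paths.genome, {g.chrom: g.contig for g in genes})
    for ext in (".fai",):  # stale index would shadow a regenerated genome
        idx = Path(str(paths.genome) + ext)
        if idx.exists():
            idx.unlink()
    sio.write_gtf(paths.gtf, [t for g in genes for t in g.transcripts])
    sio.write_events(paths.events, [g.event for g in genes])
    sio.write_domains(paths.domains, [d for g in genes for d in g.domains])
    sio.write_go(paths.go, ann)
    sio.write_gmt(paths.gmt, coll)

    truth_rows = [
        {
            "probeset_id": g.event.probeset_id,
            "gene_symbol": g.symbol,
            "event_class": g.event.event_class,
            "region_class": g.region_class,
            "protein_changed": g.protein_changed,
            "domain_changed": g.domain_changed,
            "affected_region": g.affected_region,
            "passes_overlap_filter": g.passes_overlap,
        }
        for g in genes
    ]
    pd.DataFrame(truth_rows).to_csv(paths.truth, sep="\t", index=False)

    summary = {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "planted_pathway": "PW_PLANTED",
        "n_protein_changed": sum(g.protein_changed for g in genes),
        "n_domain_changed": sum(g.domain_changed for g in genes),
        "n_overlap_pass": sum(g.passes_overlap for g in genes),
    }
    with open(paths.summary, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
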