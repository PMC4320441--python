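"""Domain-level impact calls from the inclusion→exclusion residue liftover.

Domains are annotated on the inclusion (reference) protein.  The residue
correspondence implied by a :class:`~spliceimpact.models.ResidueDiff` is
piecewise trivial: prefix residues map by identity, suffix residues map with a
constant offset, and every residue of the altered block is absent from the
exclusion isoform.  Status vocabulary per domain:

* ``lost`` — every domain residue is absent;
* ``truncated`` — the conserved sequence ends inside the domain with nothing
  conserved after it (no common suffix), i.e. the protein was shortened into
  the domain;
* ``internally_altered`` — some but not all domain residues fall in the
  altered block (frameshift-divergent residues count as altered: a divergent
  sequence cannot preserve the domain);
* ``intact`` — the domain does not touch the altered block.

When no domain changes but the protein does, the alteration is placed as
N-terminal, C-terminal or linker (inter-domain) relative to the annotated
domains; proteins without annotated domains use the position of the altered
block itself (touching residue 0 → N-terminal, touching the last residue or
beyond → C-terminal, else linker).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .models import DomainHit, DomainStatus, ResidueDiff


@dataclass(frozen=True)
class ResidueMap:
    """Correspondence from inclusion residue index to exclusion index."""

    prefix_len: int
    suffix_len: int
    len_incl: int
    len_excl: int

    @classmethod
    def from_diff(cls, diff: ResidueDiff) -> "ResidueMap":
        return cls(diff.prefix_len, diff.suffix_len, diff.len_incl, diff.len_excl)

    def __call__(self, i: int) -> Optional[int]:
        if not (0 <= i < self.len_incl):
            raise IndexError(f"residue {i} outside protein of length {self.len_incl}")
        if i < self.prefix_len:
            return i
        if i >= self.len_incl - self.suffix_len:
            return i + (self.len_excl - self.len_incl)
        return None

    @property
    def altered_block(self) -> Tuple[int, int]:
        """Inclusion residues absent from the exclusion isoform (half-open)."""
        return (self.prefix_len, self.len_incl - self.suffix_len)


def residue_map(diff: ResidueDiff) -> ResidueMap:
    return ResidueMap.from_diff(diff)


def _status(domain: DomainHit, rmap: ResidueMap) -> str:
    ds, de = domain.res_start, domain.res_end
    if de > rmap.len_incl:
        raise ValueError(
            f"domain {domain.accession} [{ds},{de}) exceeds protein "
            f"length {rmap.len_incl}"
        )
    bs, be = rmap.altered_block
    overlap = min(de, be) - max(ds, bs)
    if overlap <= 0:
        return "intact"
    if overlap == de - ds:
        return "lost"
    if rmap.suffix_len == 0 and ds < bs < de:
        return "truncated"
    return "internally_altered"


def classify_impact(
    domains: Sequence[DomainHit], diff: ResidueDiff, rmap: Optional[ResidueMap] = None
) -> Tuple[List[DomainStatus], bool, str]:
    """Per-domain statuses plus the event-level affected-region call.

    Returns ``(statuses, domain_changed, affected_region)`` where
    ``affected_region`` is one of domain/n_term/c_term/linker/none.
    """
    rmap = rmap or ResidueMap.from_diff(diff)
    statuses = [DomainStatus(domain=d, status=_status(d, rmap)) for d in domains]
    domain_changed = any(s.status != "intact" for s in statuses)
    if not diff.protein_changed:
        return statuses, False, "none"
    if domain_changed:
        return statuses, True, "domain"

    bs, be = rmap.altered_block
    if bs == be:  # pure insertion in the exclusion isoform: use the breakpoint
        lo, hi = bs, bs + 1
    else:
        lo, hi = bs, be
    if domains:
        first_start = min(d.res_start for d in domains)
        last_end = max(d.res_end for d in domains)
        if hi <= first_start:
            return statuses, False, "n_term"
        if lo >= last_end:
            return statuses, False, "c_term"
        return statuses, False, "linker"
    if lo == 0:
        return statuses, False, "n_term"
    if hi >= rmap.len_incl:
        return statuses, False, "c_term"
    return statuses, False, "linker"
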