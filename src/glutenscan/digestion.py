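"""In-silico chymotryptic digestion and peptide-to-protein mapping.

Chymotrypsin cleaves C-terminally of Tyr, Phe, Trp or Leu unless the
next residue is Pro.  Digestion with up to ``max_missed`` missed
cleavages yields every concatenation of at most ``max_missed + 1``
adjacent fully-cleaved fragments.

Coordinates are 0-based; a cleavage site ``i`` means the peptide bond
after ``sequence[i]`` is cut.  The C-terminus is never reported as a
site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqio import ProteinRecord


@dataclass(frozen=True)
class DigestParams:
    """Protease specificity and digest filters.

    Defaults encode chymotrypsin: cleave after Y/F/W/L unless followed
    by P, up to two missed cleavages, no length filter.  ``equate_il``
    folds Ile onto Leu for peptide-protein matching (off by default:
    search-engine output is sequence-level).
    """

    cleave_after: frozenset[str] = frozenset("YFWL")
    block_next: frozenset[str] = frozenset("P")
    max_missed: int = 2
    min_len: int = 1
    max_len: int | None = None
    equate_il: bool = False

    def __post_init__(self) -> None:
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len is not None and self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")

    def normalize(self, peptide: str) -> str:
        return peptide.replace("I", "L") if self.equate_il else peptide


def cleavage_sites(sequence: str, params: DigestParams = DigestParams()) -> list[int]:
    """Return 0-based positions after which the protease cuts.

    Position ``i`` is a site iff ``sequence[i]`` is a cleavable residue
    and it is not followed by a blocking residue.  The terminal residue
    is never a site (there is no bond after it).
    """
    if not sequence:
        raise ValueError("empty sequence")
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in params.cleave_after and sequence[i + 1] not in params.block_next:
            sites.append(i)
    return sites


def fragments(sequence: str, params: DigestParams = DigestParams()) -> list[str]:
    """Fully-cleaved (0 missed cleavage) fragments, in order."""
    sites = cleavage_sites(sequence, params)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    return [sequence[bounds[k] : bounds[k + 1]] for k in range(len(bounds) - 1)]


def digest(sequence: str, params: DigestParams = DigestParams()) -> dict[str, int]:
    """Digest a sequence; return ``{peptide: missed_cleavage_count}``.

    Peptides are concatenations of up to ``max_missed + 1`` adjacent
    fully-cleaved fragments.  When the same peptide string arises at
    several positions, the minimum missed-cleavage count is kept.  The
    length filter is applied last.
    """
    frags = fragments(sequence, params)
    out: dict[str, int] = {}
    for start in range(len(frags)):
        for missed in range(min(params.max_missed, len(frags) - start - 1) + 1):
            pep = "".join(frags[start : start + missed + 1])
            if len(pep) < params.min_len:
                continue
            if params.max_len is not None and len(pep) > params.max_len:
                continue
            if pep not in out or missed < out[pep]:
                out[pep] = missed
    return out


@dataclass
class PeptideProteinMap:
    """Peptide -> parent-accession mapping with uniqueness classification.

    ``parents`` maps each mapped peptide to the set of accessions whose
    in-silico digest contains it; ``orphans`` lists query peptides with
    no parent in the database (recorded, never an error).
    """

    parents: dict[str, frozenset[str]] = field(default_factory=dict)
    orphans: list[str] = field(default_factory=list)

    def is_unique(self, peptide: str) -> bool:
        return len(self.parents[peptide]) == 1

    @property
    def unique_peptides(self) -> set[str]:
        return {p for p, accs in self.parents.items() if len(accs) == 1}

    def proteins_to_peptides(self) -> dict[str, frozenset[str]]:
        """Invert the map: accession -> set of mapped peptides."""
        inv: dict[str, set[str]] = {}
        for pep, accs in self.parents.items():
            for acc in accs:
                inv.setdefault(acc, set()).add(pep)
        return {acc: frozenset(peps) for acc, peps in inv.items()}

    def restrict(self, peptides: Iterable[str]) -> "PeptideProteinMap":
        keep = set(peptides)
        return PeptideProteinMap(
            parents={p: a for p, a in self.parents.items() if p in keep},
            orphans=[p for p in self.orphans if p in keep],
        )


def map_peptides(
    peptides: Iterable[str],
    proteins: Sequence[ProteinRecord],
    params: DigestParams = DigestParams(),
    digests: Mapping[str, dict[str, int]] | None = None,
) -> PeptideProteinMap:
    """Map observed peptides onto the proteins whose digest contains them.

    A protein is a parent of a peptide iff the peptide occurs in
    ``digest(protein.sequence, params)`` (exact string match; I/L folded
    together only when ``params.equate_il``).  ``digests`` may supply
    precomputed per-accession digests to avoid recomputation.
    """
    if digests is None:
        digests = {p.accession: digest(p.sequence, params) for p in proteins}
    index: dict[str, set[str]] = {}
    for p in proteins:
        for pep in digests[p.accession]:
            index.setdefault(params.normalize(pep), set()).add(p.accession)
    result = PeptideProteinMap()
    for pep in sorted(set(peptides)):
        accs = index.get(params.normalize(pep))
        if accs:
            result.parents[pep] = frozenset(accs)
        else:
            result.orphans.append(pep)
    return result
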