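"""Allergen-homologue detection.

Two complementary screens against each candidate protein:

* **full** — optimal pairwise alignment of the whole allergen sequence
  (local Smith-Waterman by default); a call passes when identity and
  query coverage clear configurable minima (defaults 50% / 0.5).  Raw
  identity and coverage are always reported so users can re-threshold.
* **window** — the Codex-style sliding screen: every 80-residue window
  of the allergen (step 1) is aligned locally against the candidate and
  windows with identity strictly greater than 35% are counted; one or
  more hits passes.  Queries shorter than the window cannot be screened
  this way and are flagged ``too_short_for_window``.

Candidate proteins flagged as fragments (partial sequences) are
discarded from homologue calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._align import AlignmentResult, align
from .seqio import ProteinRecord


@dataclass(frozen=True)
class HomologyConfig:
    """Alignment and acceptance parameters for homologue screening."""

    window: int = 80
    step: int = 1
    window_identity_threshold: float = 35.0  # strict '>' as applied
    full_mode: str = "local"
    full_identity_min: float = 50.0
    full_coverage_min: float = 0.5
    gap_open: int = -10
    gap_extend: int = -1
    identity_denominator: str = "columns"  # or "shorter"


@dataclass(frozen=True)
class HomologyHit:
    """One (allergen, candidate) evaluation by one method."""

    query_id: str
    subject_accession: str
    method: str  # "full" | "window"
    percent_identity: float
    coverage: float
    window_hits: int
    passed: bool
    flags: frozenset[str] = frozenset()


def _identity(res: AlignmentResult, a_len: int, b_len: int, denominator: str) -> float:
    if denominator == "columns":
        return res.percent_identity
    if denominator == "shorter":
        short = min(a_len, b_len)
        return 100.0 * res.matches / short if short else 0.0
    raise ValueError(f"unknown identity denominator {denominator!r}")


def pairwise_identity(
    a: str,
    b: str,
    mode: str = "local",
    config: HomologyConfig = HomologyConfig(),
) -> tuple[float, int, float]:
    """(percent identity, aligned length, coverage of ``a``).

    Identity counts matches over alignment columns (gaps included) of
    the best alignment; with no positive-scoring local alignment the
    identity is 0.  Deterministic for fixed scoring parameters.
    """
    res = align(a, b, mode=mode, gap_open=config.gap_open, gap_extend=config.gap_extend)
    coverage = (res.a_end - res.a_start) / len(a)
    return _identity(res, len(a), len(b), config.identity_denominator), res.aligned_length, coverage


@dataclass
class WindowScanResult:
    """Sliding-window screen of one query against one subject."""

    window_hits: int
    best_identity: float
    n_windows: int
    window_identities: list[float] = field(default_factory=list)
    too_short_for_window: bool = False

    @property
    def passed(self) -> bool:
        return self.window_hits >= 1


def window_scan(
    query: str,
    subject: str,
    config: HomologyConfig = HomologyConfig(),
) -> WindowScanResult:
    """Slide ``window``-mers of the query over the subject.

    Each query window is aligned locally against the whole subject;
    windows whose identity strictly exceeds the threshold count as
    hits.  A query shorter than the window is flagged, not an error
    (such sequences can only be screened by the full-sequence method).
    """
    w = config.window
    if len(query) < w:
        return WindowScanResult(0, 0.0, 0, [], too_short_for_window=True)
    identities = []
    for start in range(0, len(query) - w + 1, config.step):
        res = align(
            query[start : start + w],
            subject,
            mode="local",
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
        identities.append(_identity(res, w, len(subject), config.identity_denominator))
    hits = sum(1 for x in identities if x > config.window_identity_threshold)
    return WindowScanResult(hits, max(identities), len(identities), identities)


def find_homologues(
    allergens: Sequence[ProteinRecord],
    proteome: Sequence[ProteinRecord],
    config: HomologyConfig = HomologyConfig(),
) -> list[HomologyHit]:
    """Screen every allergen against every non-fragment candidate.

    Each (allergen, candidate) pair yields a ``full`` hit record and,
    when the allergen is long enough, a ``window`` hit record; ``passed``
    carries each method's criterion.  Fragment-flagged candidates are
    discarded up front, so they can never appear as homologue calls.
    """
    hits: list[HomologyHit] = []
    subjects = [p for p in proteome if not p.is_fragment]
    for q in allergens:
        for s in subjects:
            ident, _, cov = pairwise_identity(q.sequence, s.sequence, config.full_mode, config)
            hits.append(
                HomologyHit(
                    query_id=q.accession,
                    subject_accession=s.accession,
                    method="full",
                    percent_identity=ident,
                    coverage=cov,
                    window_hits=0,
                    passed=ident >= config.full_identity_min and cov >= config.full_coverage_min,
                )
            )
            scan = window_scan(q.sequence, s.sequence, config)
            flags = frozenset({"too_short_for_window"}) if scan.too_short_for_window else frozenset()
            hits.append(
                HomologyHit(
                    query_id=q.accession,
                    subject_accession=s.accession,
                    method="window",
                    percent_identity=scan.best_identity,
                    coverage=0.0 if scan.too_short_for_window else 1.0,
                    window_hits=scan.window_hits,
                    passed=scan.passed,
                    flags=flags,
                )
            )
    return hits


def common_homologues(hits: Sequence[HomologyHit]) -> set[tuple[str, str]]:
    """(query, subject) pairs passing both the full and window methods."""
    passed: dict[str, set[tuple[str, str]]] = {"full": set(), "window": set()}
    for h in hits:
        if h.passed:
            passed[h.method].add((h.query_id, h.subject_accession))
    return passed["full"] & passed["window"]
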