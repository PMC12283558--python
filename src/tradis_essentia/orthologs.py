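"""Reciprocal-best-hit orthology and cross-species essentiality agreement.

Orthologs between two proteomes are called as bidirectional best hits
(bbh) over filtered tabular similarity searches: hits must pass an
E-value ceiling (default 1e-5) and query/subject coverage floors
(default 70%, inclusive); proteins with within-proteome paralogs are
excluded because a paralog may complement a disrupted copy and confound
the essentiality comparison.  Surviving 1:1 pairs are joined with the
per-species essentiality calls to tabulate agreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import TabularHit

__all__ = [
    "MAX_EVALUE",
    "MIN_COVERAGE_PCT",
    "OrthologPair",
    "EssentialityComparison",
    "filter_hits",
    "best_hits",
    "reciprocal_pairs",
    "exclude_paralogs",
    "compare_essentiality",
]

log = logging.getLogger(__name__)

MAX_EVALUE = 1e-5
MIN_COVERAGE_PCT = 70.0

#: Agreement/mismatch categories, in reporting order.
CATEGORIES = (
    "agree_essential",
    "agree_non_essential",
    "agree_unclear",
    "essential_vs_non_essential",
    "non_essential_vs_essential",
    "mismatch_with_unclear",
)
_AGREE = CATEGORIES[:3]


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    bitscore_ab: float
    bitscore_ba: float
    passed_filters: bool = True


@dataclass
class EssentialityComparison:
    """Per-pair calls in both species plus aggregate category counts."""

    pairs: list[tuple[OrthologPair, str, str]]
    counts: dict[str, int]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_agree(self) -> int:
        return sum(self.counts[c] for c in _AGREE)

    @property
    def n_mismatch(self) -> int:
        return self.n_pairs - self.n_agree

    @property
    def agreement_percent(self) -> int:
        import math

        if not self.pairs:
            return 0
        return int(math.floor(self.n_agree / self.n_pairs * 100 + 0.5))

    def summary(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_agree": self.n_agree,
            "n_mismatch": self.n_mismatch,
            "agreement_percent": self.agreement_percent,
            "counts": dict(self.counts),
        }


def filter_hits(
    hits: Iterable[TabularHit],
    max_evalue: float = MAX_EVALUE,
    min_qcov: float = MIN_COVERAGE_PCT,
    min_scov: float = MIN_COVERAGE_PCT,
) -> list[TabularHit]:
    """Keep hits passing the E-value ceiling and coverage floors.

    Coverage bounds are inclusive ("at least 70%"); self-hits
    (query == subject) are dropped.
    """
    return [
        h
        for h in hits
        if h.query_id != h.subject_id
        and h.evalue <= max_evalue
        and h.query_coverage_pct >= min_qcov
        and h.subject_coverage_pct >= min_scov
    ]


def best_hits(hits: Iterable[TabularHit]) -> dict[str, TabularHit]:
    """Single best hit per query, with a deterministic tie-break.

    Best by bit score; ties broken by lower E-value, then higher percent
    identity, then lexicographically smallest subject id.
    """
    best: dict[str, TabularHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    return best


def _hit_rank(h: TabularHit) -> tuple:
    return (-h.bitscore, h.evalue, -h.percent_identity, h.subject_id)


def reciprocal_pairs(
    best_ab: Mapping[str, TabularHit], best_ba: Mapping[str, TabularHit]
) -> list[OrthologPair]:
    """Emit (a, b) iff a's best hit is b and b's best hit is a."""
    pairs = []
    for a, hit_ab in best_ab.items():
        b = hit_ab.subject_id
        hit_ba = best_ba.get(b)
        if hit_ba is not None and hit_ba.subject_id == a:
            pairs.append(
                OrthologPair(
                    gene_a=a,
                    gene_b=b,
                    bitscore_ab=hit_ab.bitscore,
                    bitscore_ba=hit_ba.bitscore,
                )
            )
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def paralogous_proteins(
    self_hits: Iterable[TabularHit],
    max_evalue: float = MAX_EVALUE,
    min_qcov: float = MIN_COVERAGE_PCT,
    min_scov: float = MIN_COVERAGE_PCT,
) -> set[str]:
    """Proteins with a non-self within-proteome hit passing the filters.

    Both sides of a qualifying within-proteome hit are paralogous.
    """
    flagged: set[str] = set()
    for h in filter_hits(self_hits, max_evalue, min_qcov, min_scov):
        flagged.add(h.query_id)
        flagged.add(h.subject_id)
    return flagged


def exclude_paralogs(
    pairs: Sequence[OrthologPair],
    self_hits_a: Iterable[TabularHit],
    self_hits_b: Iterable[TabularHit],
    max_evalue: float = MAX_EVALUE,
    min_qcov: float = MIN_COVERAGE_PCT,
    min_scov: float = MIN_COVERAGE_PCT,
) -> list[OrthologPair]:
    """Drop every pair touching a protein that has a paralog."""
    para_a = paralogous_proteins(self_hits_a, max_evalue, min_qcov, min_scov)
    para_b = paralogous_proteins(self_hits_b, max_evalue, min_qcov, min_scov)
    kept = [
        p for p in pairs if p.gene_a not in para_a and p.gene_b not in para_b
    ]
    log.info(
        "paralog filter removed %d of %d pairs", len(pairs) - len(kept), len(pairs)
    )
    return kept


def _category(call_a: str, call_b: str) -> str:
    if call_a == call_b:
        return {
            "essential": "agree_essential",
            "non_essential": "agree_non_essential",
            "unclear": "agree_unclear",
        }[call_a]
    if "unclear" in (call_a, call_b):
        return "mismatch_with_unclear"
    if call_a == "essential":
        return "essential_vs_non_essential"
    return "non_essential_vs_essential"


def compare_essentiality(
    pairs: Sequence[OrthologPair],
    calls_a: Mapping[str, str],
    calls_b: Mapping[str, str],
) -> EssentialityComparison:
    """Join ortholog pairs with calls in both species and tabulate.

    Every paired gene must have a call; a missing gene raises an error
    naming it.  Category counts partition the pair list.
    """
    joined = []
    counts = {c: 0 for c in CATEGORIES}
    for p in pairs:
        if p.gene_a not in calls_a:
            raise KeyError(f"gene {p.gene_a!r} has no call in species A table")
        if p.gene_b not in calls_b:
            raise KeyError(f"gene {p.gene_b!r} has no call in species B table")
        ca, cb = calls_a[p.gene_a], calls_b[p.gene_b]
        counts[_category(ca, cb)] += 1
        joined.append((p, ca, cb))
    return EssentialityComparison(pairs=joined, counts=counts)
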