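"""Rearrangement detection, RF/RS statistics and arrangement typing.

A gene counts as rearranged relative to a benchmark order when its cyclic
neighbor context (the unordered pair of flanking gene names, after both
orders are restricted to their shared genes) differs from the benchmark's,
or when its strand differs. The rearrangement frequency RF(g) of a gene
over a cohort is the percentage of genomes containing g in which g is
rearranged, truncated (not rounded) to two decimals — the convention under
which 30/38 prints as 78.94. The rearrangement score RS of one genome is
the weighted count of position and strand changes, default weights (1, 1).

Genes absent from a genome are skipped, never counted as rearranged, so
partial mitogenomes are first-class inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .errors import IncomparableOrdersError, UnclassifiableOrderError
from .gene_order import (
    CircularGeneOrder,
    gryllidea_arrangement,
    insect_typical,
    neighbors,
    orders_equal,
)


@dataclass(frozen=True)
class GeneRearrangementStatus:
    gene: str
    position_changed: bool
    strand_changed: bool

    @property
    def rearranged(self) -> bool:
        return self.position_changed or self.strand_changed


@dataclass
class RearrangementReport:
    """Cohort-level RF per gene and RS per genome against one benchmark."""

    cohort_size: int
    reference: str
    weights: tuple[float, float]
    rf: dict[str, float]
    n_present: dict[str, int]
    n_rearranged: dict[str, int]
    rs: dict[str, float]

    def rf_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "n_genomes": self.n_present[g],
                "n_rearranged": self.n_rearranged[g],
                "RF": self.rf[g],
            }
            for g in sorted(self.rf)
        ]
        return pd.DataFrame(rows)

    def rs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"genome": k, "RS": v} for k, v in self.rs.items()]
        )


class ArrangementType(str, Enum):
    """Gryllidea arrangement classes.

    REF labels a benchmark order in reports; the classifier itself returns
    Type I for the typical arrangement (the class is defined by its
    diagnostic blocks, and the typical order carries both typical blocks).
    """

    I = "I"
    II = "II"
    III = "III"
    IVG = "IVG"
    REF = "REF"
    NOVEL = "NOVEL"


@dataclass(frozen=True)
class ArrangementClassification:
    label: ArrangementType
    nsE_inverted: bool
    rRNA_block: str  # "16S-trnV-12S" (typical), "16S-12S-trnV" (transposed), "other"


def rearranged_genes(
    order: CircularGeneOrder, ref: CircularGeneOrder
) -> list[GeneRearrangementStatus]:
    """Per-gene rearrangement status of *order* against benchmark *ref*.

    Comparison is restricted to the shared genes; each shared gene's
    unordered neighbor-name pair within the restricted cycles is compared,
    plus its strand.
    """
    shared = set(order.names) & set(ref.names)
    if len(shared) < 3:
        raise IncomparableOrdersError(
            f"orders share only {len(shared)} genes; need at least 3"
        )
    a = order.restricted(shared)
    b = ref.restricted(shared)
    statuses = []
    for g in sorted(shared):
        ua, da = neighbors(a, g)
        ub, db = neighbors(b, g)
        position_changed = {ua.name, da.name} != {ub.name, db.name}
        strand_changed = a.gene(g).strand != b.gene(g).strand
        statuses.append(GeneRearrangementStatus(g, position_changed, strand_changed))
    return statuses


def rearrangement_score(
    order: CircularGeneOrder,
    ref: CircularGeneOrder = insect_typical,
    weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """RS = sum over shared genes of w_pos*[position changed] + w_strand*[strand changed]."""
    w_pos, w_strand = weights
    return float(
        sum(
            w_pos * s.position_changed + w_strand * s.strand_changed
            for s in rearranged_genes(order, ref)
        )
    )


def _truncate2(x: float) -> float:
    return math.floor(x * 100.0) / 100.0


def rearrangement_frequency(
    cohort: list[CircularGeneOrder],
    ref: CircularGeneOrder = insect_typical,
    weights: tuple[float, float] = (1.0, 1.0),
) -> RearrangementReport:
    """RF per gene and RS per genome over a cohort, against one benchmark.

    RF(g) = 100 * (#genomes with g rearranged) / (#genomes containing g),
    truncated to 2 decimals. Genomes lacking g are excluded from both
    numerator and denominator.
    """
    if not cohort:
        raise ValueError("empty cohort")
    n_present: dict[str, int] = {}
    n_re: dict[str, int] = {}
    rs: dict[str, float] = {}
    for i, order in enumerate(cohort):
        label = order.label or f"genome_{i}"
        statuses = rearranged_genes(order, ref)
        w_pos, w_strand = weights
        rs[label] = float(
            sum(w_pos * s.position_changed + w_strand * s.strand_changed for s in statuses)
        )
        for s in statuses:
            n_present[s.gene] = n_present.get(s.gene, 0) + 1
            n_re[s.gene] = n_re.get(s.gene, 0) + int(s.rearranged)
    rf = {g: _truncate2(100.0 * n_re[g] / n_present[g]) for g in n_present}
    return RearrangementReport(
        cohort_size=len(cohort),
        reference=ref.label,
        weights=weights,
        rf=rf,
        n_present=n_present,
        n_rearranged=n_re,
        rs=rs,
    )


_DIAGNOSTIC = ("trnN", "trnS1", "trnE", "trnV", "12S", "16S")

_EVIDENCE_TO_TYPE = {
    (False, "16S-trnV-12S"): ArrangementType.I,
    (True, "16S-trnV-12S"): ArrangementType.II,
    (True, "16S-12S-trnV"): ArrangementType.III,
    (False, "16S-12S-trnV"): ArrangementType.IVG,
}


def _nsE_evidence(order: CircularGeneOrder) -> bool | None:
    """True = inverted (trnE-,trnS1-,trnN-), False = typical, None = other."""
    up, down = neighbors(order, "trnS1")
    s1 = order.gene("trnS1")
    trio = (up, s1, down)
    if [g.name for g in trio] == ["trnN", "trnS1", "trnE"] and all(
        g.strand == "+" for g in trio
    ):
        return False
    if [g.name for g in trio] == ["trnE", "trnS1", "trnN"] and all(
        g.strand == "-" for g in trio
    ):
        return True
    return None


def _rrna_evidence(order: CircularGeneOrder) -> str:
    up, down = neighbors(order, "trnV")
    v = order.gene("trnV")
    if (up.name, down.name) == ("16S", "12S") and {up.strand, v.strand, down.strand} == {"-"}:
        return "16S-trnV-12S"
    if up.name == "12S" and up.strand == "-" and v.strand == "-":
        up2, _ = neighbors(order, "12S")
        if up2.name == "16S" and up2.strand == "-":
            return "16S-12S-trnV"
    return "other"


def classify_arrangement(order: CircularGeneOrder) -> ArrangementClassification:
    """Type a gene order by its two diagnostic blocks, then verify globally.

    Evidence: whether the trnN-trnS1-trnE block is locally inverted, and
    whether the rRNA block reads 16S-trnV-12S (typical) or 16S-12S-trnV
    (trnV transposed next to the control region). An order whose evidence
    matches a type but whose remaining genes deviate from that type's full
    arrangement is NOVEL. Rotation-invariant.
    """
    missing = [g for g in _DIAGNOSTIC if g not in order.names]
    if missing:
        raise UnclassifiableOrderError(
            f"cannot classify: diagnostic genes missing: {missing}"
        )
    inverted = _nsE_evidence(order)
    block = _rrna_evidence(order)
    if inverted is None:
        return ArrangementClassification(ArrangementType.NOVEL, False, block)
    candidate = _EVIDENCE_TO_TYPE.get((inverted, block))
    if candidate is None:
        return ArrangementClassification(ArrangementType.NOVEL, inverted, block)
    template = gryllidea_arrangement(candidate.value).restricted(set(order.names))
    if len(template) == len(order) and orders_equal(order, template):
        return ArrangementClassification(candidate, inverted, block)
    return ArrangementClassification(ArrangementType.NOVEL, inverted, block)
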