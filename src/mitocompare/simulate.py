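"""Synthetic annotated mitogenomes with controlled order and composition.

The generator emulates annotated circular cricket mitogenomes: 37 genes
plus a control region laid out in a requested arrangement (the typical
insect order or the Gryllidea Types I/II/III/IVG), gene lengths drawn
from the ranges observed in published cricket mitogenomes, base
composition sampled to hit a target AT% with configurable AT/GC skews,
and protein-coding genes that start and stop with configurable codons and
carry no internal stop under the invertebrate mitochondrial code. It does
not emulate tRNA secondary structure, codon-usage bias beyond the base
composition, or any read-level sequencing artifacts.

All randomness flows from the seed in the spec; identical specs serialize
to byte-identical GenBank records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .errors import SpecError
from .gene_order import (
    CircularGeneOrder,
    canonical_rotation,
    gryllidea_arrangement,
    invert_segment,
    transpose_gene,
)
from .genbank_io import AnnotatedMitogenome, GeneFeature
from .vocab import CR, KIND_BY_GENE, PCGS, TRNAS

# Per-gene length ranges (bp). ATP8, ND5, the rRNAs, the tRNAs and the
# control region follow the ranges printed for cricket mitogenomes; the
# remaining PCG ranges are package defaults typical of published cricket
# records. PCG lengths are snapped to the reading frame at sampling time.
DEFAULT_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "ATP6": (675, 684), "ATP8": (162, 171), "COI": (1530, 1545),
    "COII": (678, 690), "COIII": (786, 792), "CYTB": (1134, 1143),
    "ND1": (939, 948), "ND2": (1020, 1035), "ND3": (351, 360),
    "ND4": (1329, 1341), "ND4L": (288, 297), "ND5": (1725, 1734),
    "ND6": (495, 522), "12S": (627, 785), "16S": (1193, 1375),
    CR: (500, 2000),
}
TRNA_LENGTH_RANGE: tuple[int, int] = (48, 71)


@dataclass(frozen=True)
class MitogenomeSpec:
    """Recipe for one synthetic mitogenome.

    ``gene_order`` is an arrangement label (REF/I/II/III/IVG) or an
    explicit :class:`CircularGeneOrder`. Composition targets are the
    deposited-strand expectations for the non-CR portion; the control
    region is generated AT-enriched above the genome target.
    """

    seed: int
    gene_order: CircularGeneOrder | str = "REF"
    at_percent: float = 72.0
    at_skew: float = 0.04
    gc_skew: float = -0.33
    cr_at_percent: float = 85.0
    length_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    start_codons: dict[str, str] = field(default_factory=dict)
    stop_codons: dict[str, str] = field(default_factory=dict)
    spacer_max: int = 5
    label: str | None = None

    def resolve_order(self) -> CircularGeneOrder:
        if isinstance(self.gene_order, CircularGeneOrder):
            return canonical_rotation(self.gene_order)
        return canonical_rotation(gryllidea_arrangement(self.gene_order))

    def length_range(self, gene: str) -> tuple[int, int]:
        if gene in self.length_ranges:
            return self.length_ranges[gene]
        if gene in TRNAS:
            return TRNA_LENGTH_RANGE
        return DEFAULT_LENGTH_RANGES[gene]

    def start_codon(self, gene: str) -> str:
        if gene in self.start_codons:
            return self.start_codons[gene].upper()
        return "TTG" if gene == "ND1" else "ATG"

    def stop_codon(self, gene: str) -> str:
        return self.stop_codons.get(gene, "TAA").upper()


def _base_probs(at_percent: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """P(A), P(C), P(G), P(T) from the marginal targets."""
    if not 0.0 < at_percent < 100.0:
        raise SpecError(f"at_percent {at_percent} outside (0, 100)")
    if not (-1.0 <= at_skew <= 1.0 and -1.0 <= gc_skew <= 1.0):
        raise SpecError("skew targets must lie in [-1, 1]")
    at = at_percent / 100.0
    gc = 1.0 - at
    p = np.array(
        [
            at * (1.0 + at_skew) / 2.0,  # A
            gc * (1.0 - gc_skew) / 2.0,  # C
            gc * (1.0 + gc_skew) / 2.0,  # G
            at * (1.0 - at_skew) / 2.0,  # T
        ]
    )
    if np.any(p <= 0.0):
        raise SpecError(
            "infeasible composition: some base has probability 0 "
            f"(at%={at_percent}, at_skew={at_skew}, gc_skew={gc_skew})"
        )
    return p / p.sum()


_STOPS = ("TAA", "TAG")


def _random_seq(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _random_cds(
    rng: np.random.Generator, length: int, probs: np.ndarray, start: str, stop: str
) -> str:
    """Sense-strand CDS: start codon, internal-stop-free body, stop codon.

    ``stop`` may be TAA/TAG or an incomplete terminator T/TA; the body is
    rejection-sampled codon-wise against TAA/TAG."""
    n_body = (length - 3 - len(stop)) // 3
    codons = []
    while len(codons) < n_body:
        c = _random_seq(rng, 3, probs)
        if c not in _STOPS:
            codons.append(c)
    return start + "".join(codons) + stop


def _sample_length(rng, spec: MitogenomeSpec, gene: str) -> int:
    lo, hi = spec.length_range(gene)
    if not 0 < lo <= hi:
        raise SpecError(f"{gene}: bad length range {lo}..{hi}")
    length = int(rng.integers(lo, hi + 1))
    if gene in PCGS:
        stop = spec.stop_codon(gene)
        if stop not in ("TAA", "TAG", "TA", "T"):
            raise SpecError(f"{gene}: unsupported stop codon {stop!r}")
        # snap down to the frame: length = 3k + (0, 1 or 2 trailing nt)
        rem = len(stop) % 3
        length -= (length - rem) % 3
        length = max(length, 6 + rem)
    return length


def generate_mitogenome(spec: MitogenomeSpec) -> AnnotatedMitogenome:
    """Deterministically generate one annotated circular mitogenome."""
    rng = np.random.default_rng(spec.seed)
    order = spec.resolve_order()
    probs = _base_probs(spec.at_percent, spec.at_skew, spec.gc_skew)
    cr_probs = _base_probs(
        min(spec.cr_at_percent, 99.0), spec.at_skew, spec.gc_skew
    )

    # CR sits after the last listed gene (between 12S and trnI in the
    # typical arrangement, and right after the transposed trnV in III/IVG).
    layout: list[tuple[str, str]] = [(g.name, g.strand) for g in order.genes]
    layout.append((CR, "+"))

    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for name, strand in layout:
        if spec.spacer_max > 0:
            spacer = int(rng.integers(0, spec.spacer_max + 1))
            if spacer:
                chunks.append(_random_seq(rng, spacer, probs))
                pos += spacer
        # Composition asymmetry is a property of the deposited strand, so a
        # minus-strand gene's sense sequence is sampled from the mirrored
        # distribution (P(A)<->P(T), P(C)<->P(G)); placing its reverse
        # complement restores the deposited-strand target, and the gene's
        # own sense strand shows the opposite skews — the pattern real
        # per-gene composition tables exhibit.
        gene_probs = probs if strand == "+" else probs[::-1]
        if name == CR:
            sense = _random_seq(rng, _sample_length(rng, spec, CR), cr_probs)
        elif name in PCGS:
            sense = _random_cds(
                rng,
                _sample_length(rng, spec, name),
                gene_probs,
                spec.start_codon(name),
                spec.stop_codon(name),
            )
        else:
            sense = _random_seq(rng, _sample_length(rng, spec, name), gene_probs)
        placed = str(Seq(sense).reverse_complement()) if strand == "-" else sense
        features.append(
            GeneFeature(name, KIND_BY_GENE[name], pos, pos + len(placed), strand)
        )
        chunks.append(placed)
        pos += len(placed)

    ident = spec.label or (
        f"SIM-{spec.gene_order if isinstance(spec.gene_order, str) else 'custom'}"
        f"-{spec.seed}"
    )
    return AnnotatedMitogenome(
        id=ident,
        sequence="".join(chunks),
        features=features,
        circular=True,
        source="synthetic mitogenome",
    )


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a cohort of synthetic mitogenomes.

    The default per-type counts (7 Type I, 23 Type II, 7 Type III,
    1 Type IVG) reproduce the composition of the 38 complete cricket
    mitogenomes whose arrangements the package's statistics target.
    """

    seed: int
    counts: dict[str, int] = field(
        default_factory=lambda: {"I": 7, "II": 23, "III": 7, "IVG": 1}
    )
    base: MitogenomeSpec | None = None

    def total(self) -> int:
        return sum(self.counts.values())


def generate_cohort(spec: CohortSpec) -> list[AnnotatedMitogenome]:
    """Generate a cohort; labels encode the true type (e.g. SIM-II-07)."""
    if spec.total() < 1:
        raise SpecError("cohort must contain at least one genome")
    base = spec.base or MitogenomeSpec(seed=0)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.total())
    genomes = []
    i = 0
    for type_label, count in spec.counts.items():
        if count < 0:
            raise SpecError(f"negative count for type {type_label}")
        for k in range(count):
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            member = replace(
                base,
                seed=child_seed,
                gene_order=type_label,
                label=f"SIM-{type_label}-{k:02d}",
            )
            genomes.append(generate_mitogenome(member))
            i += 1
    return genomes


@dataclass(frozen=True)
class Invert:
    """Local inversion of the contiguous block from ``first`` to ``last``."""

    first: str
    last: str


@dataclass(frozen=True)
class Transpose:
    """Move ``gene`` (strand unchanged) to just after ``after``."""

    gene: str
    after: str


def apply_rearrangement(
    order: CircularGeneOrder, op: Invert | Transpose
) -> CircularGeneOrder:
    """Apply one rearrangement event to a gene order."""
    if isinstance(op, Invert):
        return invert_segment(order, op.first, op.last)
    if isinstance(op, Transpose):
        return transpose_gene(order, op.gene, op.after)
    raise TypeError(f"unknown rearrangement op {op!r}")
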