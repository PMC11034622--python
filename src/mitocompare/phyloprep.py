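"""Phylogenomic matrix preparation.

Takes per-gene alignments (produced upstream by an aligner/trimmer),
applies codon-position masks, concatenates them into a supermatrix with
missing taxa gap-filled, and exports partition definitions for tree
software (NEXUS sets block or RAxML-style). Alignment and tree inference
themselves are external tools; this module only speaks their formats.

The shipped ``gryllidea11`` preset encodes the eleven-partition scheme
used for cricket mitogenome phylogenomics — one partition per PCG with
ND5+ND4 and ATP8+ND6 merged — with codon sites 1+2 retained (site 3
dropped, as saturated) for ATP6, COII, COIII, ND1, ND3 and ND6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import FrameError
from .vocab import PCGS

# Fixed gene order of concatenation (a package convention; it affects
# charset coordinates only, never the inference itself).
CONCAT_ORDER: tuple[str, ...] = (
    "ATP6", "ATP8", "COI", "COII", "COIII", "CYTB",
    "ND1", "ND2", "ND3", "ND4", "ND5", "ND6", "ND4L",
)

_ALPHABET = set("ACGTN-")


@dataclass
class GeneAlignment:
    """One gene's multiple alignment: taxon -> aligned sense-strand row."""

    gene: str
    seqs: dict[str, str]
    mask: str = "all"  # "all" or "sites12"; records what was applied

    def __post_init__(self):
        if not self.seqs:
            raise ValueError(f"{self.gene}: empty alignment")
        widths = {len(s) for s in self.seqs.values()}
        if len(widths) != 1:
            raise ValueError(f"{self.gene}: rows of unequal length {sorted(widths)}")
        self.seqs = {t: s.upper() for t, s in self.seqs.items()}
        bad = set("".join(self.seqs.values())) - _ALPHABET
        if bad:
            raise ValueError(f"{self.gene}: illegal characters {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(next(iter(self.seqs.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.seqs)


def read_fasta_alignment(source, gene: str) -> GeneAlignment:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(source, "fasta")}
    return GeneAlignment(gene=gene, seqs=seqs)


def write_fasta_alignment(aln: GeneAlignment, handle) -> None:
    for taxon, seq in aln.seqs.items():
        handle.write(f">{taxon}\n")
        for i in range(0, len(seq), 60):
            handle.write(seq[i : i + 60] + "\n")


def codon_position_mask(
    aln: GeneAlignment, mask: str, frame_start: int = 0
) -> GeneAlignment:
    """Apply a codon-position mask to an alignment.

    ``sites12`` keeps codon positions 1 and 2 (drops every third column)
    counting from ``frame_start``; ``all`` is the identity. Columns before
    ``frame_start`` are kept untouched.
    """
    if mask == "all":
        return aln
    if mask != "sites12":
        raise ValueError(f"unknown mask {mask!r}")
    if (aln.width - frame_start) % 3 != 0:
        raise FrameError(
            f"{aln.gene}: {aln.width - frame_start} columns from frame start "
            "not divisible by 3"
        )
    keep = [
        i
        for i in range(aln.width)
        if i < frame_start or (i - frame_start) % 3 != 2
    ]
    return GeneAlignment(
        gene=aln.gene,
        seqs={t: "".join(s[i] for i in keep) for t, s in aln.seqs.items()},
        mask="sites12",
    )


@dataclass(frozen=True)
class Partition:
    name: str
    genes: tuple[str, ...]


@dataclass
class PartitionScheme:
    """Named gene groups plus the per-gene codon-position masks."""

    partitions: tuple[Partition, ...]
    gene_masks: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for p in self.partitions:
            overlap = seen & set(p.genes)
            if overlap:
                raise ValueError(f"genes in multiple partitions: {sorted(overlap)}")
            seen |= set(p.genes)

    def mask_for(self, gene: str) -> str:
        return self.gene_masks.get(gene, "all")


_GRYLLIDEA11_GROUPS = (
    ("ND1", ("ND1",)),
    ("ND2", ("ND2",)),
    ("ND3", ("ND3",)),
    ("ND5_ND4", ("ND5", "ND4")),
    ("ATP6", ("ATP6",)),
    ("ATP8_ND6", ("ATP8", "ND6")),
    ("COI", ("COI",)),
    ("COII", ("COII",)),
    ("COIII", ("COIII",)),
    ("CYTB", ("CYTB",)),
    ("ND4L", ("ND4L",)),
)

SITES12_GENES: tuple[str, ...] = ("ATP6", "COII", "COIII", "ND1", "ND3", "ND6")

PRESETS: dict[str, PartitionScheme] = {
    "gryllidea11": PartitionScheme(
        partitions=tuple(Partition(n, g) for n, g in _GRYLLIDEA11_GROUPS),
        gene_masks={g: "sites12" for g in SITES12_GENES},
    )
}


@dataclass
class Supermatrix:
    """Concatenated alignment with a column map back to (gene, column)."""

    taxa: tuple[str, ...]
    seqs: dict[str, str]
    column_map: tuple[tuple[str, int], ...]
    gene_ranges: dict[str, tuple[int, int]]  # 0-based half-open

    @property
    def width(self) -> int:
        return len(self.column_map)

    def split(self) -> list[GeneAlignment]:
        """Recover the per-gene alignments (gap-filled rows included)."""
        out = []
        for gene, (a, b) in self.gene_ranges.items():
            out.append(
                GeneAlignment(
                    gene=gene, seqs={t: self.seqs[t][a:b] for t in self.taxa}
                )
            )
        return out


def concatenate(
    alns: list[GeneAlignment], taxa: list[str] | None = None
) -> tuple[Supermatrix, dict[str, tuple[int, int]]]:
    """Concatenate gene alignments into a supermatrix.

    Genes are laid out in the fixed :data:`CONCAT_ORDER` (unlisted genes
    appended alphabetically). Taxa default to the sorted union; a taxon
    absent from a gene gets '-' across that gene's block (missing data).
    """
    if not alns:
        raise ValueError("no alignments to concatenate")
    by_gene: dict[str, GeneAlignment] = {}
    for a in alns:
        if a.gene in by_gene:
            raise ValueError(f"duplicate alignment for gene {a.gene}")
        by_gene[a.gene] = a
    ordered = [g for g in CONCAT_ORDER if g in by_gene]
    ordered += sorted(set(by_gene) - set(CONCAT_ORDER))
    if taxa is None:
        taxa = sorted({t for a in alns for t in a.taxa})
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")

    rows = {t: [] for t in taxa}
    column_map: list[tuple[str, int]] = []
    gene_ranges: dict[str, tuple[int, int]] = {}
    offset = 0
    for gene in ordered:
        a = by_gene[gene]
        for t in taxa:
            rows[t].append(a.seqs.get(t, "-" * a.width))
        column_map.extend((gene, i) for i in range(a.width))
        gene_ranges[gene] = (offset, offset + a.width)
        offset += a.width
    sm = Supermatrix(
        taxa=tuple(taxa),
        seqs={t: "".join(parts) for t, parts in rows.items()},
        column_map=tuple(column_map),
        gene_ranges=gene_ranges,
    )
    return sm, gene_ranges


def build_supermatrix(
    alns: list[GeneAlignment],
    scheme: PartitionScheme | str = "gryllidea11",
    apply_masks: bool = True,
    frame_start: int = 0,
) -> tuple[Supermatrix, PartitionScheme]:
    """Mask (per the scheme), then concatenate.

    With ``apply_masks`` the site-3 columns of sites12 genes are physically
    removed before concatenation, so the exported charsets are contiguous
    ranges that tile the matrix exactly.
    """
    if isinstance(scheme, str):
        scheme = PRESETS[scheme]
    work = []
    masks: dict[str, str] = {}
    for a in alns:
        mask = scheme.mask_for(a.gene)
        if apply_masks and mask == "sites12":
            work.append(codon_position_mask(a, "sites12", frame_start))
            masks[a.gene] = "applied"
        else:
            work.append(a)
            if mask != "all":
                masks[a.gene] = mask
    sm, _ = concatenate(work)
    applied = PartitionScheme(partitions=scheme.partitions, gene_masks=masks)
    return sm, applied


def _charset_ranges(
    scheme: PartitionScheme, sm: Supermatrix
) -> list[tuple[str, list[str]]]:
    """1-based range strings per partition; sites12 genes left unmasked in
    the matrix get the codon-step syntax ``a-b\\3, a+1-b\\3``."""
    out = []
    for p in scheme.partitions:
        ranges = []
        for gene in p.genes:
            if gene not in sm.gene_ranges:
                continue
            a, b = sm.gene_ranges[gene]
            a1, b1 = a + 1, b  # 1-based inclusive
            if scheme.mask_for(gene) == "sites12":
                ranges.append(f"{a1}-{b1}\\3")
                ranges.append(f"{a1 + 1}-{b1}\\3")
            else:
                ranges.append(f"{a1}-{b1}")
        if ranges:
            out.append((p.name, ranges))
    if not out:
        raise ValueError("scheme has no partitions present in the matrix")
    return out


def export_partitions(
    scheme: PartitionScheme, sm: Supermatrix, dialect: str = "raxml"
) -> str:
    """Partition definitions as text: ``raxml`` (``DNA, name = a-b``) or
    ``nexus_sets`` (a ``begin sets; charset ...; end;`` block)."""
    charsets = _charset_ranges(scheme, sm)
    if dialect == "raxml":
        return "".join(
            f"DNA, {name} = {', '.join(ranges)}\n" for name, ranges in charsets
        )
    if dialect == "nexus_sets":
        lines = ["#NEXUS", "begin sets;"]
        lines += [
            f"    charset {name} = {' '.join(ranges)};" for name, ranges in charsets
        ]
        lines.append("end;")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


def write_phylip(sm: Supermatrix, handle) -> None:
    """Relaxed PHYLIP (name, two spaces, full row)."""
    handle.write(f"{len(sm.taxa)} {sm.width}\n")
    for t in sm.taxa:
        handle.write(f"{t}  {sm.seqs[t]}\n")


def read_phylip(source) -> dict[str, str]:
    if isinstance(source, str) and "\n" in source:
        lines = source.splitlines()
    else:
        handle = open(source) if isinstance(source, str) else source
        lines = handle.read().splitlines()
    header = lines[0].split()
    ntax, ncol = int(header[0]), int(header[1])
    seqs: dict[str, str] = {}
    for line in lines[1 : 1 + ntax]:
        name, seq = line.split(None, 1)
        seq = seq.replace(" ", "")
        if len(seq) != ncol:
            raise ValueError(f"{name}: row width {len(seq)} != header {ncol}")
        seqs[name] = seq
    return seqs
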