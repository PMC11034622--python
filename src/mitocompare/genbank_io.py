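"""Reading and writing annotated mitogenomes.

GenBank flat files are parsed and emitted through Biopython; what this
module adds is the domain model (:class:`AnnotatedMitogenome`) and the
strict normalization of heterogeneous gene labels onto the canonical
37-gene vocabulary. Coordinates are 0-based half-open internally and
converted to/from GenBank's 1-based inclusive convention at the boundary;
features spanning the circular origin keep ``end > genome_length`` with
``wraps_origin`` set, which keeps arithmetic on circular molecules
unambiguous.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import vocab
from .errors import (
    BoundsError,
    DuplicateGeneError,
    GenomeFormatError,
    MissingGeneError,
    UnknownGeneError,
)
from .vocab import CR, GENES, KIND_BY_GENE, normalize_gene_name

_FEATURE_KEY_TO_KIND = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "CR"}
_KIND_TO_FEATURE_KEY = {v: k for k, v in _FEATURE_KEY_TO_KIND.items()}


@dataclass(frozen=True)
class GeneFeature:
    """One gene on a circular mitogenome.

    ``start``/``end`` are 0-based half-open on the deposited (plus) strand;
    a feature wrapping the origin of a genome of length L has
    ``start < L <= end < 2L`` and ``wraps_origin=True``.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str
    wraps_origin: bool = False

    def __post_init__(self):
        if self.name not in vocab.ALL_FEATURES:
            raise UnknownGeneError(self.name)
        if KIND_BY_GENE[self.name] != self.kind:
            raise ValueError(f"kind {self.kind!r} inconsistent with gene {self.name!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise BoundsError(f"bad feature extent {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedMitogenome:
    """A circular mitochondrial genome with typed, stranded gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    source: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise GenomeFormatError(f"sequence contains non-ACGTN characters: {bad}")
        L = len(self.sequence)
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise DuplicateGeneError(f"gene {f.name} annotated more than once")
            seen.add(f.name)
            if f.start >= L:
                raise BoundsError(f"{f.name}: start {f.start} >= genome length {L}")
            if f.end > L and not f.wraps_origin:
                raise BoundsError(f"{f.name}: end {f.end} beyond genome length {L}")
            if f.wraps_origin and f.end >= 2 * L:
                raise BoundsError(f"{f.name}: wrapping end {f.end} >= 2x length")
        self.features.sort(key=lambda f: (f.start, f.name))

    @property
    def genome_length(self) -> int:
        return len(self.sequence)

    @property
    def gene_names(self) -> set[str]:
        return {f.name for f in self.features if f.name != CR}

    @property
    def is_complete(self) -> bool:
        """True when all 37 canonical genes are annotated."""
        return self.gene_names == set(GENES)

    def feature(self, gene: str) -> GeneFeature:
        for f in self.features:
            if f.name == gene:
                return f
        raise MissingGeneError(f"gene {gene} not annotated in {self.id}")

    def has_gene(self, gene: str) -> bool:
        return any(f.name == gene for f in self.features)


def _normalize_feature_label(feat: SeqFeature, kind: str) -> str:
    """Try /gene, /product then /note; raise UnknownGeneError on failure."""
    candidates = []
    for q in ("gene", "product", "note"):
        candidates.extend(feat.qualifiers.get(q, []))
    if not candidates:
        raise UnknownGeneError("<no qualifier>", f"{feat.type} feature has no label")
    last_err: UnknownGeneError | None = None
    for raw in candidates:
        try:
            return normalize_gene_name(raw, kind_hint=kind)
        except UnknownGeneError as err:
            last_err = err
    assert last_err is not None
    raise last_err


def _location_to_coords(loc, length: int) -> tuple[int, int, str, bool]:
    strand = "-" if loc.strand == -1 else "+"
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if (
            len(parts) == 2
            and int(parts[1].end) == length
            and int(parts[0].start) == 0
        ):
            # join(x..L, 1..y): wraps the origin
            return int(parts[1].start), length + int(parts[0].end), strand, True
        raise GenomeFormatError(f"unsupported compound location {loc}")
    return int(loc.start), int(loc.end), strand, False


def read_genbank(source) -> AnnotatedMitogenome:
    """Parse one GenBank record into an :class:`AnnotatedMitogenome`.

    ``source`` may be a path, an open handle, or the flat-file text itself.
    CDS/tRNA/rRNA features must carry a /gene, /product or /note qualifier
    mappable to the canonical vocabulary; anything unmappable is a hard
    :class:`UnknownGeneError` (misnamed genes silently corrupt the
    downstream gene-order statistics). ``gene`` and ``source`` features are
    annotation duplicates and are ignored; ``misc_feature`` is consulted
    only as a control-region candidate.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        record = SeqIO.read(source, "genbank")
    except Exception as err:  # Biopython raises bare ValueError on bad input
        raise GenomeFormatError(f"could not parse GenBank record: {err}") from err

    length = len(record.seq)
    if length == 0:
        raise GenomeFormatError("record has no sequence (empty ORIGIN)")
    circular = record.annotations.get("topology", "linear") == "circular"

    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type in ("source", "gene", "misc_RNA"):
            continue
        if feat.type == "misc_feature":
            try:
                name = _normalize_feature_label(feat, "CR")
            except UnknownGeneError:
                continue
            if name != CR:
                continue
            kind = "CR"
        elif feat.type in _FEATURE_KEY_TO_KIND:
            kind = _FEATURE_KEY_TO_KIND[feat.type]
            name = CR if kind == "CR" else _normalize_feature_label(feat, kind)
        else:
            continue
        start, end, strand, wraps = _location_to_coords(feat.location, length)
        features.append(
            GeneFeature(name, KIND_BY_GENE[name], start, end, strand, wraps)
        )

    return AnnotatedMitogenome(
        id=record.id if record.id != "<unknown id>" else record.name,
        sequence=str(record.seq),
        features=features,
        circular=circular,
        source=record.description or "",
    )


def _coords_to_location(f: GeneFeature, length: int):
    strand = -1 if f.strand == "-" else 1
    if f.wraps_origin:
        return CompoundLocation(
            [
                SimpleLocation(f.start, length, strand),
                SimpleLocation(0, f.end - length, strand),
            ]
        )
    return SimpleLocation(f.start, f.end, strand)


_PRODUCTS = {
    "trnL1": "tRNA-Leu(CUN)", "trnL2": "tRNA-Leu(UUR)",
    "trnS1": "tRNA-Ser(AGN)", "trnS2": "tRNA-Ser(UCN)",
    "12S": "12S ribosomal RNA", "16S": "16S ribosomal RNA",
    CR: "control region",
}


def write_genbank(genome: AnnotatedMitogenome, handle=None) -> str:
    """Emit a GenBank flat file (returned as text; also written to *handle*).

    Locations are 1-based inclusive, minus-strand features wrapped in
    complement(), origin-wrapping features emitted as join(x..L,1..y).
    """
    L = genome.genome_length
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description=genome.source or "mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "data_file_division": "INV",
            "date": "01-JAN-2024",  # fixed so identical genomes serialize identically
        },
    )
    for f in genome.features:
        if f.start >= L or (not f.wraps_origin and f.end > L):
            raise BoundsError(f"{f.name} outside sequence of length {L}")
        qualifiers = {"gene": [f.name]}
        if f.name in _PRODUCTS:
            qualifiers["product"] = [_PRODUCTS[f.name]]
        record.features.append(
            SeqFeature(
                _coords_to_location(f, L),
                type=_KIND_TO_FEATURE_KEY[f.kind],
                qualifiers=qualifiers,
            )
        )
    out = io.StringIO()
    SeqIO.write(record, out, "genbank")
    text = out.getvalue()
    if handle is not None:
        handle.write(text)
    return text


def extract_gene_sequence(genome: AnnotatedMitogenome, gene: str) -> str:
    """Return a gene's sequence on its own coding/sense strand.

    Plus-strand features are sliced directly; minus-strand features are
    reverse-complemented; origin-wrapping features concatenate the two arcs
    before orientation.
    """
    f = genome.feature(gene)
    L = genome.genome_length
    if f.wraps_origin:
        raw = genome.sequence[f.start :] + genome.sequence[: f.end - L]
    else:
        raw = genome.sequence[f.start : f.end]
    if f.strand == "-":
        return str(Seq(raw).reverse_complement())
    return raw


def genes_to_fasta(genome: AnnotatedMitogenome, genes=None, handle=None) -> str:
    """Multi-FASTA of per-gene sense-strand sequences (all genes by default)."""
    names = genes if genes is not None else [f.name for f in genome.features]
    chunks = []
    for name in names:
        seq = extract_gene_sequence(genome, name)
        chunks.append(f">{genome.id}|{name}\n")
        chunks.extend(seq[i : i + 60] + "\n" for i in range(0, len(seq), 60))
    text = "".join(chunks)
    if handle is not None:
        handle.write(text)
    return text


def reverse_complement_genome(genome: AnnotatedMitogenome) -> AnnotatedMitogenome:
    """The same molecule deposited on the opposite strand.

    Every feature keeps its sense-strand sequence (strand labels flip and
    coordinates mirror), which makes this the natural invariance check for
    per-gene extraction and composition statistics.
    """
    L = genome.genome_length
    rc = str(Seq(genome.sequence).reverse_complement())
    flipped = []
    for f in genome.features:
        strand = "-" if f.strand == "+" else "+"
        if f.wraps_origin:
            new = replace(f, start=2 * L - f.end, end=2 * L - f.start, strand=strand)
        else:
            new = replace(f, start=L - f.end, end=L - f.start, strand=strand)
        flipped.append(new)
    return AnnotatedMitogenome(
        id=genome.id,
        sequence=rc,
        features=flipped,
        circular=genome.circular,
        source=genome.source,
    )
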