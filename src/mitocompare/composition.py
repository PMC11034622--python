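"""Nucleotide composition, strand asymmetry, and start/stop codon reports.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C), computed over the
A+C+G+T counts of a sequence (Ns excluded from every denominator, so the
AT% and GC% of a sequence sum to 100). Whole-genome statistics are taken
on the deposited strand; per-gene statistics on each gene's own sense
strand — the convention under which minus-strand genes (ND1, ND4, ND4L,
ND5 and the two rRNAs in the typical insect arrangement) show positive
GC-skew while the genome's is negative. Pooled tRNA rows group the tRNAs
by deposited-strand orientation: plus = light (L), minus = heavy (H).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import GenomeFormatError
from .genbank_io import AnnotatedMitogenome, extract_gene_sequence
from .vocab import CR, PCGS, RRNAS


@dataclass(frozen=True)
class CompositionProfile:
    label: str
    a: int
    c: int
    g: int
    t: int
    n: int
    at_percent: float
    gc_percent: float
    at_skew: float
    gc_skew: float
    at_skew_degenerate: bool = False
    gc_skew_degenerate: bool = False

    @property
    def counted(self) -> int:
        return self.a + self.c + self.g + self.t


def profile(seq: str, label: str = "") -> CompositionProfile:
    """Composition profile of one nucleotide sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise GenomeFormatError(f"non-ACGTN characters: {sorted(bad)}")
    a, c, g, t, n = (s.count(x) for x in "ACGTN")
    total = a + c + g + t
    if total == 0:
        raise ValueError(f"{label or 'sequence'}: no unambiguous bases")
    at, gc = a + t, g + c
    return CompositionProfile(
        label=label,
        a=a, c=c, g=g, t=t, n=n,
        at_percent=100.0 * at / total,
        gc_percent=100.0 * gc / total,
        at_skew=(a - t) / at if at else 0.0,
        gc_skew=(g - c) / gc if gc else 0.0,
        at_skew_degenerate=(at == 0),
        gc_skew_degenerate=(gc == 0),
    )


def genome_table(
    genome: AnnotatedMitogenome, exclude_cr: bool = False
) -> list[CompositionProfile]:
    """Table-1-shaped profiles: whole genome, each PCG/rRNA (sense strand),
    then pooled tRNAs(L) and tRNAs(H).

    ``exclude_cr`` drops the annotated control region span from the
    whole-genome row (per-gene rows never include it). Missing genes are
    simply absent; a pooled tRNA row is omitted when its strand group is
    empty. Output order is deterministic.
    """
    whole = genome.sequence
    if exclude_cr and genome.has_gene(CR):
        f = genome.feature(CR)
        if f.wraps_origin:
            L = genome.genome_length
            whole = genome.sequence[f.end - L : f.start]
        else:
            whole = genome.sequence[: f.start] + genome.sequence[f.end :]
    rows = [profile(whole, genome.id)]

    for gene in PCGS + RRNAS:
        if genome.has_gene(gene):
            rows.append(profile(extract_gene_sequence(genome, gene), gene))

    pools = {"+": [], "-": []}
    for f in genome.features:
        if f.kind == "tRNA":
            pools[f.strand].append(extract_gene_sequence(genome, f.name))
    if pools["+"]:
        rows.append(profile("".join(pools["+"]), "tRNAs(L)"))
    if pools["-"]:
        rows.append(profile("".join(pools["-"]), "tRNAs(H)"))
    return rows


def table_frame(rows: list[CompositionProfile], precision: bool = True) -> pd.DataFrame:
    """Profiles as a DataFrame; with ``precision`` the percentages are
    printed to 1 decimal and the skews to 3 (full precision otherwise)."""
    recs = []
    for r in rows:
        recs.append(
            {
                "label": r.label,
                "AT%": round(r.at_percent, 1) if precision else r.at_percent,
                "GC%": round(r.gc_percent, 1) if precision else r.gc_percent,
                "AT-skew": round(r.at_skew, 3) if precision else r.at_skew,
                "GC-skew": round(r.gc_skew, 3) if precision else r.gc_skew,
            }
        )
    return pd.DataFrame(recs)


_TYPICAL_STARTS = {"ATA", "ATT", "ATC", "ATG", "TTG", "GTG"}


@dataclass(frozen=True)
class CodonEnds:
    gene: str
    start_codon: str
    stop_codon: str
    incomplete_stop: bool
    unusual_start: bool


def codon_ends(genome: AnnotatedMitogenome) -> list[CodonEnds]:
    """Start and stop codon of every annotated PCG, read off the sense
    strand and reported verbatim (unusual starts flagged, never altered).

    A CDS whose length is not a multiple of 3 ends in an incomplete stop
    (T or TA, completed by polyadenylation in vivo) and is flagged.
    """
    out = []
    for f in genome.features:
        if f.kind != "PCG":
            continue
        seq = extract_gene_sequence(genome, f.name)
        if len(seq) < 6:
            raise GenomeFormatError(
                f"{f.name}: CDS of {len(seq)} nt too short to have start and stop"
            )
        start = seq[:3]
        rem = len(seq) % 3
        stop = seq[-3:] if rem == 0 else seq[-rem:]
        out.append(
            CodonEnds(
                gene=f.name,
                start_codon=start,
                stop_codon=stop,
                incomplete_stop=(rem != 0),
                unusual_start=(start not in _TYPICAL_STARTS),
            )
        )
    return sorted(out, key=lambda e: e.gene)
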