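"""Canonical gene vocabulary for insect mitogenomes.

The 37-gene inventory (13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus
the control region, and a synonym table that maps the heterogeneous labels
found in GenBank records onto one canonical id per gene.

Leucine and serine tRNAs are split by codon family (trnL1 = CUN,
trnL2 = UUR, trnS1 = AGN, trnS2 = UCN); a bare "tRNA-Leu"/"tRNA-Ser"
without an anticodon or family qualifier is ambiguous and is rejected
rather than guessed.
"""

from __future__ import annotations

import re

from .errors import UnknownGeneError

PCGS: tuple[str, ...] = (
    "ATP6", "ATP8", "COI", "COII", "COIII", "CYTB",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
)

TRNAS: tuple[str, ...] = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG",
    "trnH", "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP",
    "trnS1", "trnS2", "trnT", "trnW", "trnY", "trnV",
)

RRNAS: tuple[str, ...] = ("12S", "16S")

CR = "CR"

GENES: tuple[str, ...] = PCGS + TRNAS + RRNAS          # the 37-gene alphabet
ALL_FEATURES: tuple[str, ...] = GENES + (CR,)

KIND_BY_GENE: dict[str, str] = (
    {g: "PCG" for g in PCGS}
    | {g: "tRNA" for g in TRNAS}
    | {g: "rRNA" for g in RRNAS}
    | {CR: "CR"}
)

# Single-letter amino acid -> tRNA id (unambiguous ones only).
_AA_TO_TRNA = {
    "ala": "trnA", "arg": "trnR", "asn": "trnN", "asp": "trnD",
    "cys": "trnC", "gln": "trnQ", "glu": "trnE", "gly": "trnG",
    "his": "trnH", "ile": "trnI", "lys": "trnK", "met": "trnM",
    "phe": "trnF", "pro": "trnP", "thr": "trnT", "trp": "trnW",
    "tyr": "trnY", "val": "trnV",
}

_SYNONYMS: dict[str, str] = {
    # protein-coding genes
    "coi": "COI", "cox1": "COI", "co1": "COI", "coxi": "COI",
    "cytochrome c oxidase subunit 1": "COI",
    "cytochrome c oxidase subunit i": "COI",
    "coii": "COII", "cox2": "COII", "co2": "COII", "coxii": "COII",
    "cytochrome c oxidase subunit 2": "COII",
    "cytochrome c oxidase subunit ii": "COII",
    "coiii": "COIII", "cox3": "COIII", "co3": "COIII", "coxiii": "COIII",
    "cytochrome c oxidase subunit 3": "COIII",
    "cytochrome c oxidase subunit iii": "COIII",
    "cytb": "CYTB", "cob": "CYTB", "cyb": "CYTB", "cytochrome b": "CYTB",
    "atp6": "ATP6", "atpase6": "ATP6", "atp synthase f0 subunit 6": "ATP6",
    "atp8": "ATP8", "atpase8": "ATP8", "atp synthase f0 subunit 8": "ATP8",
    "nd1": "ND1", "nad1": "ND1", "nadh1": "ND1",
    "nadh dehydrogenase subunit 1": "ND1",
    "nd2": "ND2", "nad2": "ND2", "nadh2": "ND2",
    "nadh dehydrogenase subunit 2": "ND2",
    "nd3": "ND3", "nad3": "ND3", "nadh3": "ND3",
    "nadh dehydrogenase subunit 3": "ND3",
    "nd4": "ND4", "nad4": "ND4", "nadh4": "ND4",
    "nadh dehydrogenase subunit 4": "ND4",
    "nd4l": "ND4L", "nad4l": "ND4L",
    "nadh dehydrogenase subunit 4l": "ND4L",
    "nd5": "ND5", "nad5": "ND5", "nadh5": "ND5",
    "nadh dehydrogenase subunit 5": "ND5",
    "nd6": "ND6", "nad6": "ND6", "nadh6": "ND6",
    "nadh dehydrogenase subunit 6": "ND6",
    # rRNAs
    "12s": "12S", "rrns": "12S", "s-rrna": "12S", "srrna": "12S",
    "12s rrna": "12S", "12s ribosomal rna": "12S",
    "small subunit ribosomal rna": "12S",
    "16s": "16S", "rrnl": "16S", "l-rrna": "16S", "lrrna": "16S",
    "16s rrna": "16S", "16s ribosomal rna": "16S",
    "large subunit ribosomal rna": "16S",
    # control region
    "cr": "CR", "d-loop": "CR", "control region": "CR",
    "a+t-rich region": "CR", "t+a-rich region": "CR", "at-rich region": "CR",
    "a+t rich region": "CR", "t+a rich region": "CR",
}

# leucine/serine families, keyed by codon-family or anticodon strings
_LS_FAMILY = {
    "cun": "trnL1", "uur": "trnL2", "ttr": "trnL2",
    "agn": "trnS1", "ucn": "trnS2", "tcn": "trnS2",
    # anticodons as they appear in products, e.g. tRNA-Leu(TAA)
    "tag": "trnL1", "uag": "trnL1", "taa": "trnL2", "uaa": "trnL2",
    "gct": "trnS1", "gcu": "trnS1", "tga": "trnS2", "uga": "trnS2",
}

_TRNA_RE = re.compile(r"^trna[-_ ]?([a-z]{3})\s*(?:\(([a-z]{3})\))?$")


def normalize_gene_name(raw: str, kind_hint: str | None = None) -> str:
    """Map a raw feature label to its canonical gene id.

    Parameters
    ----------
    raw:
        The label as found in a record (``/gene`` or ``/product`` value).
    kind_hint:
        Optional feature kind ("PCG", "tRNA", "rRNA", "CR") from the
        feature key; used only for disambiguation, never to override
        an explicit label.

    Raises
    ------
    UnknownGeneError
        If the label cannot be mapped, including ambiguous bare
        "tRNA-Leu"/"tRNA-Ser" labels.
    """
    if not raw or not raw.strip():
        raise UnknownGeneError(raw, "empty gene label")
    key = " ".join(raw.strip().lower().split())

    if key in _SYNONYMS:
        return _SYNONYMS[key]

    # direct canonical forms: trnA ... trnV, trnL1/trnL2/trnS1/trnS2
    m = re.match(r"^trn([a-z])([12])?$", key)
    if m:
        letter, num = m.group(1).upper(), m.group(2)
        cand = f"trn{letter}{num or ''}"
        if cand in TRNAS:
            return cand
        if cand in ("trnL", "trnS"):
            raise UnknownGeneError(raw, f"{raw!r} ambiguous between 1/2 family")
        raise UnknownGeneError(raw)

    m = _TRNA_RE.match(key)
    if m:
        aa, anticodon = m.groups()
        if aa in ("leu", "ser"):
            if anticodon and anticodon in _LS_FAMILY:
                return _LS_FAMILY[anticodon]
            raise UnknownGeneError(
                raw, f"{raw!r} ambiguous: leucine/serine tRNA without codon family"
            )
        if aa in _AA_TO_TRNA:
            return _AA_TO_TRNA[aa]
        raise UnknownGeneError(raw)

    if kind_hint == "CR" and ("rich" in key or "loop" in key or "control" in key):
        return CR

    raise UnknownGeneError(raw)
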