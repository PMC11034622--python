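"""Codon usage (RSCU), amino-acid frequencies, and Nei-Gojobori dN/dS.

The genetic code defaults to the invertebrate mitochondrial table
(translation table 5: AGA/AGG = Ser, ATA = Met, TGA = Trp; stops TAA and
TAG only, leaving 62 sense codons). Synonymous families follow the tRNA
families, i.e. leucine is split into CUN (trnL1) and UUR (trnL2) and
serine into AGN (trnS1) and UCN (trnS2); RSCU of a codon is its count
divided by the uniform-usage expectation within its family, so the family
RSCU values sum to the family size.

dN/dS is the original Nei-Gojobori (1986) pathway method: per-codon
synonymous/nonsynonymous site fractions (changes to stop codons count as
nonsynonymous), equal-weight averaging over the substitution pathways
between differing codons (pathways through stop codons excluded),
Jukes-Cantor correction of the proportions, and a codon-based Z-test of
selection with a bootstrap standard error over codon sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import norm

from .errors import CorrectionUndefinedError, NumtSuspectError

_BASES = "TCAG"


def _three_letter(aa: str) -> str:
    return {
        "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
        "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
        "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
        "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    }[aa]


@dataclass(frozen=True)
class GeneticCode:
    """A codon table plus the synonymous-family partition used for RSCU."""

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    start_codons: frozenset[str]
    families: dict[str, tuple[str, ...]]
    family_of: dict[str, str]

    @classmethod
    def from_table(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = dict(table.forward_table)
        stops = frozenset(table.stop_codons)
        fam_of: dict[str, str] = {}
        for codon, aa in codon_to_aa.items():
            name = _three_letter(aa)
            if aa == "L":
                name = "Leu(UUR)" if codon.startswith("TT") else "Leu(CUN)"
            elif aa == "S":
                name = "Ser(AGN)" if codon.startswith("AG") else "Ser(UCN)"
            fam_of[codon] = name
        families: dict[str, tuple[str, ...]] = {}
        for codon in sorted(fam_of):
            families.setdefault(fam_of[codon], ())
            families[fam_of[codon]] += (codon,)
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            stop_codons=stops,
            start_codons=frozenset(table.start_codons),
            families=families,
            family_of=fam_of,
        )

    def translate(self, codon: str) -> str:
        return "*" if codon in self.stop_codons else self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


INVERTEBRATE_MITO = GeneticCode.from_table(5)


def _codons(seq: str) -> list[str]:
    """Full codons of a CDS, trailing incomplete codon dropped."""
    s = seq.upper().replace("U", "T")
    return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


def _countable(codon: str) -> bool:
    return set(codon) <= set("ACGT")


@dataclass
class RSCUTable:
    code: GeneticCode
    counts: dict[str, int]
    rscu: dict[str, float]
    family_totals: dict[str, int]

    def to_frame(self, rna: bool = True) -> pd.DataFrame:
        """Codon, family, count and RSCU; codons in RNA form by default
        (the display convention of codon-usage figures)."""
        rows = []
        for fam, codons in sorted(self.code.families.items()):
            for codon in codons:
                rows.append(
                    {
                        "codon": codon.replace("T", "U") if rna else codon,
                        "family": fam,
                        "count": self.counts[codon],
                        "RSCU": self.rscu[codon],
                    }
                )
        return pd.DataFrame(rows)


def rscu(cds_set: list[str], code: GeneticCode = INVERTEBRATE_MITO) -> RSCUTable:
    """Relative synonymous codon usage over a set of sense-strand CDS.

    Stop codons and codons containing ambiguous bases are excluded.
    rscu(c) = count(c) / (family_total / family_size); a family with zero
    usage gets RSCU 0 for all members (flagged by its zero total).
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    counts = {c: 0 for c in code.family_of}
    for cds in cds_set:
        if len(cds) < 3:
            raise ValueError("CDS shorter than one codon")
        for codon in _codons(cds):
            if _countable(codon) and not code.is_stop(codon):
                counts[codon] += 1
    totals = {
        fam: sum(counts[c] for c in codons) for fam, codons in code.families.items()
    }
    values = {}
    for fam, codons in code.families.items():
        size, total = len(codons), totals[fam]
        for c in codons:
            values[c] = counts[c] * size / total if total else 0.0
    return RSCUTable(code=code, counts=counts, rscu=values, family_totals=totals)


def amino_acid_frequencies(
    cds_set: list[str], code: GeneticCode = INVERTEBRATE_MITO
) -> dict[str, float]:
    """Percentage of counted codons per amino-acid family (Leu and Ser
    reported per split family). Sums to 100 over non-empty input."""
    table = rscu(cds_set, code)
    grand = sum(table.family_totals.values())
    if grand == 0:
        raise ValueError("no countable codons")
    return {
        fam: 100.0 * total / grand for fam, total in sorted(table.family_totals.items())
    }


def numt_screen(cds: str, code: GeneticCode = INVERTEBRATE_MITO) -> list[int]:
    """Codon indices of internal stop codons; an empty list is a pass.

    Internal stops after conceptual translation are the working signature
    of a nuclear mitochondrial pseudogene (numt) or a frameshifted copy.
    The final codon (the legitimate stop) is not reported.
    """
    codons = _codons(cds)
    if not codons:
        raise ValueError("CDS shorter than one codon")
    return [i for i, c in enumerate(codons[:-1]) if code.is_stop(c)]


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986)
# ---------------------------------------------------------------------------


def site_counts(codon: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon.

    Each position contributes its fraction of synonymous one-nucleotide
    changes; changes creating a stop codon count as nonsynonymous.
    """
    syn = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if not code.is_stop(mutant) and code.translate(mutant) == code.translate(codon):
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def pathway_differences(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged with equal weight over single-step substitution pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    is blocked, all are used (the conventional fallback)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for perm in permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt) and nxt != c2:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if not code.is_stop(a) and not code.is_stop(b) and code.translate(
                a
            ) == code.translate(b):
                syn += 1.0
            else:
                nonsyn += 1.0
    k = len(usable)
    return syn / k, nonsyn / k


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise CorrectionUndefinedError(
            f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined"
        )
    return -0.75 * np.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class DnDsResult:
    dn: float
    ds: float
    pn: float
    ps: float
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    n_codons: int
    z_statistic: float
    p_value: float
    alternative: str


def _pair_stats(
    pairs: list[tuple[str, str]], code: GeneticCode
) -> tuple[float, float, float, float]:
    S = N = Sd = Nd = 0.0
    for c1, c2 in pairs:
        s1, n1 = site_counts(c1, code)
        s2, n2 = site_counts(c2, code)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = pathway_differences(c1, c2, code)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def _dn_ds_from_pairs(pairs, code) -> tuple[float, float]:
    S, N, Sd, Nd = _pair_stats(pairs, code)
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return _jc_correct(pn), _jc_correct(ps)


def nei_gojobori(
    seq1: str,
    seq2: str,
    code: GeneticCode = INVERTEBRATE_MITO,
    alternative: str = "neutral",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> DnDsResult:
    """Pairwise dN/dS of two aligned sense-strand CDS with a codon-based
    Z-test of selection.

    Codon columns containing gaps or ambiguous bases are deleted
    (complete deletion). Internal stop codons raise
    :class:`NumtSuspectError` — such a sequence is a pseudogene suspect,
    not a substrate for a selection test. The Z statistic is
    (dN - dS) / SE with SE estimated by bootstrap over codon columns;
    ``alternative`` selects the test: "neutral" (two-sided, H1 dN != dS),
    "positive" (H1 dN > dS) or "purifying" (H1 dN < dS).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    if alternative not in ("neutral", "positive", "purifying"):
        raise ValueError(f"unknown alternative {alternative!r}")
    c1s, c2s = _codons(seq1), _codons(seq2)
    pairs = []
    for a, b in zip(c1s, c2s):
        if "-" in a or "-" in b:
            continue
        if not (_countable(a) and _countable(b)):
            continue
        pairs.append((a, b))
    if not pairs:
        raise ValueError("no comparable codon columns after deletion")
    for idx, (a, b) in enumerate(pairs[:-1]):
        stops = [i for i, c in enumerate((a, b)) if code.is_stop(c)]
        if stops:
            raise NumtSuspectError([idx], f"internal stop at codon column {idx}")
    if code.is_stop(pairs[-1][0]) != code.is_stop(pairs[-1][1]):
        raise NumtSuspectError([len(pairs) - 1], "stop codon in only one sequence")
    if code.is_stop(pairs[-1][0]):
        pairs = pairs[:-1]  # shared terminator carries no selection signal
    if not pairs:
        raise ValueError("no codons left after dropping the stop")

    S, N, Sd, Nd = _pair_stats(pairs, code)
    pn = Nd / N if N > 0 else 0.0
    ps = Sd / S if S > 0 else 0.0
    dn = _jc_correct(pn)
    ds = _jc_correct(ps)

    rng = np.random.default_rng(seed)
    reps = []
    n = len(pairs)
    for _ in range(n_bootstrap):
        take = rng.integers(0, n, size=n)
        try:
            bdn, bds = _dn_ds_from_pairs([pairs[i] for i in take], code)
        except CorrectionUndefinedError:
            continue
        reps.append(bdn - bds)
    se = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
    z = (dn - ds) / se if se > 0 else 0.0
    if alternative == "neutral":
        p = 2.0 * float(norm.sf(abs(z)))
    elif alternative == "positive":
        p = float(norm.sf(z))
    else:
        p = float(norm.cdf(z))
    return DnDsResult(
        dn=dn,
        ds=ds,
        pn=pn,
        ps=ps,
        n_sites=N,
        s_sites=S,
        n_diffs=Nd,
        s_diffs=Sd,
        n_codons=len(pairs),
        z_statistic=z,
        p_value=min(p, 1.0),
        alternative=alternative,
    )


def dnds_matrix(
    seqs: dict[str, str],
    code: GeneticCode = INVERTEBRATE_MITO,
    seed: int = 0,
    n_bootstrap: int = 200,
) -> pd.DataFrame:
    """Pairwise dN/dS ratios for one gene across taxa (NaN where dS = 0)."""
    taxa = list(seqs)
    mat = pd.DataFrame(np.nan, index=taxa, columns=taxa, dtype=float)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            r = nei_gojobori(
                seqs[t1], seqs[t2], code, seed=seed, n_bootstrap=n_bootstrap
            )
            ratio = r.dn / r.ds if r.ds > 0 else np.nan
            mat.loc[t1, t2] = mat.loc[t2, t1] = ratio
    return mat
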