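"""Pairwise dN/dS estimation by Nei-Gojobori (1986) counting.

Builds codon alignments by back-translating a protein alignment onto the
source coding sequences (PAL2NAL-style), then estimates synonymous and
nonsynonymous substitution rates per ortholog pair:

* fractional site decomposition — each codon position contributes the
  fraction of its three possible single-nucleotide changes that are
  synonymous to S, the rest to N (changes creating stops count as
  nonsynonymous);
* pathway-averaged difference counting — codon pairs differing at two or
  three positions are resolved by averaging the synonymous/nonsynonymous
  step classification over all minimal mutational pathways, excluding
  pathways that pass through a stop codon unless every pathway does;
* Jukes-Cantor multiple-hit correction d = -3/4 ln(1 - 4p/3) applied to
  the proportions pN = Nd/N and pS = Sd/S.

omega = dN/dS carries a status flag so that a measured zero (dN = 0 with
synonymous divergence present, i.e. fixation of the amino-acid sequence)
stays distinguishable from an undefined ratio on identical sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))
BASES = "ACGT"
GAP_CODON = "---"


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; 'X' if the codon contains ambiguity letters."""
    return CODON_TO_AA.get(codon, "X")


# ---------------------------------------------------------------------------
# Site and difference counting
# ---------------------------------------------------------------------------

def count_sites(codon: str) -> tuple[float, float]:
    """Return (n, s): nonsynonymous and synonymous site counts of one codon.

    Each of the 9 single-nucleotide neighbours is classified by the standard
    code; changes creating a stop codon are nonsynonymous. n + s == 3.
    """
    codon = codon.upper()
    if codon not in CODON_TO_AA:
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        syn_here = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                syn_here += 1
        syn += syn_here / 3.0
    return 3.0 - syn, syn


def _classify_step(c1: str, c2: str) -> tuple[float, float]:
    """(nd, sd) of a single-nucleotide codon change."""
    if CODON_TO_AA[c1] == CODON_TO_AA[c2]:
        return 0.0, 1.0
    return 1.0, 0.0


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (nd, sd) between two sense codons.

    0 differences -> (0, 0); 1 difference -> direct classification;
    2-3 differences -> average over all orderings of the single-base steps,
    restricted to orderings whose intermediate codons are not stops (if all
    orderings pass through stops, average over all of them).
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c not in CODON_TO_AA or c in STOP_CODONS:
            raise ValueError(f"invalid or stop codon {c!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    if len(diff_positions) == 1:
        return _classify_step(codon_a, codon_b)

    valid: list[tuple[float, float]] = []
    through_stops: list[tuple[float, float]] = []
    for order in permutations(diff_positions):
        current = codon_a
        nd = sd = 0.0
        hits_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            step_nd, step_sd = _classify_step(current, nxt)
            nd += step_nd
            sd += step_sd
            if nxt in STOP_CODONS and nxt != codon_b:
                hits_stop = True
            current = nxt
        (through_stops if hits_stop else valid).append((nd, sd))
    pathways = valid if valid else through_stops
    nd = sum(p[0] for p in pathways) / len(pathways)
    sd = sum(p[1] for p in pathways) / len(pathways)
    return nd, sd


# Precomputed lookup tables: NG86 counting is then O(1) per codon pair.
_SITES: dict[str, tuple[float, float]] = {c: count_sites(c) for c in SENSE_CODONS}
_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}
for _a in SENSE_CODONS:
    for _b in SENSE_CODONS:
        _DIFFS[(_a, _b)] = count_differences(_a, _b)


# ---------------------------------------------------------------------------
# Codon alignment (protein-guided back-translation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonAlignment:
    """A pair of gap-containing codon sequences built from a protein alignment.

    Gaps are whole codons ("---"); stripping gaps from either row recovers
    the aligned prefix of the source CDS.
    """

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon alignment rows differ in length")

    def __len__(self) -> int:
        return len(self.codons_a)


def _codons_of(cds: str, label: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"{label}: CDS length {len(cds)} not a multiple of 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def codon_align(cdna_a: str, cdna_b: str,
                protein_alignment: tuple[str, str]) -> CodonAlignment:
    """Back-translate a pairwise protein alignment onto its coding sequences.

    Each amino-acid column maps to the source codon; a protein gap maps to
    "---". A column whose aligned residue does not match the translation of
    the corresponding codon is a hard error (guards against frameshifted or
    edited input).
    """
    prot_a, prot_b = (p.upper() for p in protein_alignment)
    if len(prot_a) != len(prot_b):
        raise ValueError("protein alignment rows differ in length")
    codons = {"A": _codons_of(cdna_a, "cdna_a"), "B": _codons_of(cdna_b, "cdna_b")}
    cursors = {"A": 0, "B": 0}
    rows: dict[str, list[str]] = {"A": [], "B": []}
    for col, (ra, rb) in enumerate(zip(prot_a, prot_b)):
        for key, residue in (("A", ra), ("B", rb)):
            if residue == "-":
                rows[key].append(GAP_CODON)
                continue
            i = cursors[key]
            if i >= len(codons[key]):
                raise ValueError(
                    f"column {col}: protein row {key} longer than its CDS")
            codon = codons[key][i]
            if translate_codon(codon) != residue:
                raise ValueError(
                    f"column {col}: codon {codon} translates to "
                    f"{translate_codon(codon)!r}, aligned residue is {residue!r}")
            rows[key].append(codon)
            cursors[key] += 1
    return CodonAlignment(tuple(rows["A"]), tuple(rows["B"]))


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteCounts:
    """Intermediate NG86 quantities for one aligned pair."""

    N: float
    S: float
    Nd: float
    Sd: float

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else 0.0

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else 0.0


@dataclass(frozen=True)
class OmegaEstimate:
    """Corrected rates and their ratio for one gene and species pair.

    ``status`` is one of:

    * ``finite``    — dN > 0 and dS > 0, omega = dN/dS;
    * ``zero``      — dN = 0 with dS > 0 (amino-acid sequence fixed);
    * ``infinite``  — dN > 0 with dS = 0;
    * ``undefined`` — no differences at all;
    * ``saturated`` — a proportion reached the Jukes-Cantor ceiling (p >= 3/4).
    """

    gene_id: str
    species_pair: str
    dN: float
    dS: float
    omega: float
    status: str

    @property
    def usable(self) -> bool:
        """True when omega is a number suitable for averaging (finite or zero)."""
        return self.status in ("finite", "zero")


def jukes_cantor(p: float) -> float:
    """Multiple-hit corrected distance for a raw proportion p < 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def count_alignment(alignment: CodonAlignment) -> SiteCounts:
    """Accumulate NG86 site and difference counts over ungapped codon columns."""
    n_tot = s_tot = nd_tot = sd_tot = 0.0
    used = 0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        if "-" in ca or "-" in cb:
            continue
        if ca not in _SITES or cb not in _SITES:
            raise ValueError(f"stop or ambiguous codon pair ({ca}, {cb})")
        na, sa = _SITES[ca]
        nb, sb = _SITES[cb]
        n_tot += (na + nb) / 2.0
        s_tot += (sa + sb) / 2.0
        nd, sd = _DIFFS[(ca, cb)]
        nd_tot += nd
        sd_tot += sd
        used += 1
    if used == 0:
        raise ValueError("alignment has no ungapped codon pairs")
    return SiteCounts(N=n_tot, S=s_tot, Nd=nd_tot, Sd=sd_tot)


def estimate_rates(alignment: CodonAlignment, gene_id: str = "",
                   species_pair: str = "") -> tuple[SiteCounts, OmegaEstimate]:
    """NG86 estimate of (dN, dS, omega) for one codon alignment."""
    counts = count_alignment(alignment)
    pn, ps = counts.pN, counts.pS
    if pn >= 0.75 or ps >= 0.75:
        est = OmegaEstimate(gene_id, species_pair, math.nan, math.nan,
                            math.nan, "saturated")
        return counts, est
    dn, ds = jukes_cantor(pn), jukes_cantor(ps)
    if dn == 0.0 and ds == 0.0:
        status, omega = "undefined", math.nan
    elif dn == 0.0:
        status, omega = "zero", 0.0
    elif ds == 0.0:
        status, omega = "infinite", math.inf
    else:
        status, omega = "finite", dn / ds
    return counts, OmegaEstimate(gene_id, species_pair, dn, ds, omega, status)


def estimate_pair(cds_a: str, cds_b: str, gene_id: str = "",
                  species_pair: str = "") -> tuple[SiteCounts, OmegaEstimate]:
    """Convenience wrapper for equal-length, gap-free coding sequences."""
    codons_a = _codons_of(cds_a, "cds_a")
    codons_b = _codons_of(cds_b, "cds_b")
    if len(codons_a) != len(codons_b):
        raise ValueError("gap-free estimation requires equal-length CDSs")
    aln = CodonAlignment(tuple(codons_a), tuple(codons_b))
    return estimate_rates(aln, gene_id, species_pair)


def omega_table(estimates: Iterable[OmegaEstimate]):
    """Omega estimates as a pandas DataFrame (one row per gene x pair)."""
    import pandas as pd

    rows = [
        {"gene_id": e.gene_id, "pair": e.species_pair, "dN": e.dN,
         "dS": e.dS, "omega": e.omega, "status": e.status}
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=["gene_id", "pair", "dN", "dS",
                                       "omega", "status"])
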