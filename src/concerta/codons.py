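"""Genetic-code machinery for Nei–Gojobori counting.

Synonymous/nonsynonymous *site* and *difference* counting at the codon
level, with the stop-codon conventions used throughout the package:

* site counting — single-base changes that would create a stop codon are
  excluded from both the numerator and the denominator of the synonymous
  fraction at that position (per-position renormalisation), so every
  position still contributes one full site (``s_i + n_i = 1``);
* difference counting — mutational pathways between two codons that pass
  through a stop codon are discarded and the per-step labels averaged over
  the surviving pathways; if every pathway is blocked, all pathways are
  used and a warning is logged.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

BASES = "ACGT"

_standard = unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, 61 sense codons of the standard code
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))


class CodonError(ValueError):
    """Raised for stop codons or codons with ambiguous/gap characters."""


def is_sense(codon: str) -> bool:
    return codon in GENETIC_CODE


def translate(cds: str, *, strip_terminal_stop: bool = False) -> tuple[str, bool]:
    """Translate an ungapped CDS with the standard code.

    Returns ``(protein, has_internal_stop)``.  Stops are written as ``*``;
    a single trailing stop is removed when *strip_terminal_stop* is set and
    does not count as internal.
    """
    if len(cds) % 3 != 0:
        raise CodonError(f"CDS length {len(cds)} is not a multiple of 3")
    cds = cds.upper()
    aa = []
    for k in range(0, len(cds), 3):
        codon = cds[k : k + 3]
        if codon in STOP_CODONS:
            aa.append("*")
        elif codon in GENETIC_CODE:
            aa.append(GENETIC_CODE[codon])
        else:
            raise CodonError(f"untranslatable codon {codon!r} at position {k + 1}")
    prot = "".join(aa)
    has_internal = "*" in (prot[:-1] if prot.endswith("*") else prot)
    if strip_terminal_stop and prot.endswith("*"):
        prot = prot[:-1]
    return prot, has_internal


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts ``(s, n)`` of one codon.

    At each position the synonymous fraction is the number of synonymous
    single-base changes divided by the number of changes that do not create
    a stop codon; ``s + n == 3`` always.
    """
    if codon not in GENETIC_CODE:
        raise CodonError(f"{codon!r} is not a sense codon")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences ``(sd, nd)``.

    All orderings of the differing positions are enumerated (1, 2 or 6
    pathways); each step is labelled synonymous or not; pathways through a
    stop codon are excluded.  ``sd + nd`` equals the number of differing
    positions.
    """
    for c in (codon_a, codon_b):
        if c not in GENETIC_CODE:
            raise CodonError(f"{c!r} is not a sense codon")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    kept: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                # label the step anyway for the all-pathway fallback
                nonsyn += 1
                cur = nxt
                continue
            aa_cur = GENETIC_CODE.get(cur)
            aa_nxt = GENETIC_CODE[nxt]
            if aa_cur is not None and aa_cur == aa_nxt:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked if through_stop else kept).append((syn, nonsyn))
    paths = kept
    if not paths:
        logger.warning(
            "all pathways between %s and %s pass through a stop; averaging over all",
            codon_a,
            codon_b,
        )
        paths = blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd
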