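"""Standard-genetic-code tables used by both the simulator and the Ks estimator.

Codons are represented either as 3-letter strings ("ATG") or as integer
indices 0..63 with base order T, C, A, G at each position (the classical
codon-table layout, so index 0 = TTT and index 63 = GGG).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

BASES = "TCAG"

CODONS: list[str] = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

# Standard genetic code, one letter per codon in TCAG order; '*' marks stops.
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

GENETIC_CODE: dict[str, str] = {c: _AA[i] for i, c in enumerate(CODONS)}
STOP_CODONS = frozenset(c for c, a in GENETIC_CODE.items() if a == "*")

AA_BY_INDEX: list[str] = list(_AA)
IS_STOP = [a == "*" for a in _AA]


def translate(cds: str) -> str:
    """Translate an in-frame CDS (no internal stops expected) to protein."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return "".join(GENETIC_CODE[cds[i : i + 3].upper()] for i in range(0, len(cds), 3))


def _single_step_neighbours(codon: str):
    """All nine single-nucleotide variants of a codon as (pos, variant)."""
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                yield pos, codon[:pos] + b + codon[pos + 1 :]


@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """Nei–Gojobori synonymous-site count of one codon.

    Each codon position contributes the fraction of its three possible
    single-nucleotide changes that preserve the amino acid; a change to a
    stop codon counts as nonsynonymous, so synonymous + nonsynonymous
    sites always total 3 per codon.
    """
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site decomposition")
    s = 0.0
    for _pos, var in _single_step_neighbours(codon):
        if GENETIC_CODE[var] == aa:
            s += 1.0 / 3.0
    return s


SYN_SITES_BY_INDEX = [0.0 if IS_STOP[i] else syn_sites(c) for i, c in enumerate(CODONS)]

# For the simulator: per codon index, the list of (position, alternative codon
# index, is_synonymous) single-nucleotide changes that do not create a stop.
MUTATION_TABLE: list[list[tuple[int, int, bool]]] = []
for _c in CODONS:
    entries: list[tuple[int, int, bool]] = []
    if GENETIC_CODE[_c] != "*":
        for _pos, _var in _single_step_neighbours(_c):
            if GENETIC_CODE[_var] != "*":
                entries.append((_pos, CODON_INDEX[_var], GENETIC_CODE[_var] == GENETIC_CODE[_c]))
    MUTATION_TABLE.append(entries)


@lru_cache(maxsize=None)
def pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts for one codon pair.

    Codons differing at several positions are resolved by averaging the
    synonymous/nonsynonymous step classification over all orderings of
    single-nucleotide steps; pathways passing through a stop codon are
    excluded (all mutational pathways are kept if every ordering is blocked,
    which cannot happen between sense codons under the standard code but
    keeps the function total).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(codon: str, remaining: tuple[int, ...], allow_stops: bool):
        """Yield (sd, nd) per pathway from codon to codon_b over remaining positions."""
        if not remaining:
            yield 0.0, 0.0
            return
        for i, pos in enumerate(remaining):
            nxt = codon[:pos] + codon_b[pos] + codon[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and len(remaining) > 1 and not allow_stops:
                continue  # intermediate stop: pathway blocked
            step_syn = GENETIC_CODE[nxt] == GENETIC_CODE[codon] and GENETIC_CODE[nxt] != "*"
            for sd, nd in walk(nxt, remaining[:i] + remaining[i + 1 :], allow_stops):
                if step_syn:
                    yield sd + 1.0, nd
                else:
                    yield sd, nd + 1.0

    paths = list(walk(codon_a, tuple(diff_pos), allow_stops=False))
    if not paths:
        paths = list(walk(codon_a, tuple(diff_pos), allow_stops=True))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd
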